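"""Locating the fluid--solid transition from an alpha-scan ensemble.

Three independent indicators are implemented:

1. diffusion: a polynomial fit to ``log10 D_eff`` vs alpha; the interior
   *inflection point* of the fit (mid-coexistence, an overestimate of the
   transition) and the point of *maximally negative curvature* (where D_eff
   starts dropping rapidly -- the end of the purely disordered branch),
2. the crossover of the pseudo-hexagon / pseudo-pentagon fractions,
   ``f6 / f5 = 1``,
3. the alpha at which the mode of the circularity distribution crosses the
   regular-pentagon value ``C(5)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .shape_metrics import C5

__all__ = ["RunSummary", "aggregate_scan", "locate_transition_Deff",
           "crossover_alpha", "mode_C5_indicator", "TransitionEstimate"]


@dataclass
class RunSummary:
    """Per-run aggregate observables entering an alpha scan."""

    alpha: float
    psi6: float | None = None
    beta: float | None = None
    d_eff: float | None = None          # None when the beta gate failed
    fractions: dict | None = None       # n -> f_n
    mode_cv: float | None = None
    nstar_peak: float | None = None
    nstar_min: float | None = None
    meta: tuple | None = None           # lattice/params fingerprint


@dataclass
class TransitionEstimate:
    alpha_inflection: float | None = None
    alpha_dropoff: float | None = None
    d_eff_at_dropoff: float | None = None
    alpha_crossover: float | None = None
    alpha_mode_C5: float | None = None
    fit: dict = field(default_factory=dict)


def _mean_sem(vals):
    v = np.array([x for x in vals if x is not None], dtype=float)
    if v.size == 0:
        return np.nan, np.nan
    sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan
    return float(v.mean()), float(sem)


def aggregate_scan(runs) -> pd.DataFrame:
    """Collapse per-run summaries into a per-alpha table (mean and SEM).

    Rows are sorted by ascending alpha and carry the run count; D_eff enters
    the average only for runs where the diffusive gate passed.  Runs grouped
    under one alpha must share the same ``meta`` fingerprint.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("no runs to aggregate")
    groups: dict[float, list[RunSummary]] = {}
    for r in runs:
        groups.setdefault(float(r.alpha), []).append(r)
    if len(groups) < 4:
        raise ValueError("need at least 4 distinct alpha values")
    rows = []
    for a in sorted(groups):
        g = groups[a]
        metas = {r.meta for r in g}
        if len(metas) > 1:
            raise ValueError(f"inconsistent lattice/params within alpha={a}")
        row = {"alpha": a, "n_runs": len(g)}
        for key in ("psi6", "beta", "mode_cv", "nstar_peak", "nstar_min"):
            row[key], row[key + "_sem"] = _mean_sem(getattr(r, key) for r in g)
        row["d_eff"], row["d_eff_sem"] = _mean_sem(r.d_eff for r in g)
        fr = [r.fractions for r in g if r.fractions]
        if fr:
            for n in range(3, 10):
                row[f"f{n}"], _ = _mean_sem(f.get(n, 0.0) for f in fr)
        rows.append(row)
    return pd.DataFrame(rows)


def locate_transition_Deff(scan: pd.DataFrame, degree: int = 4,
                           grid_step: float = 1e-4, margin: float = 0.1,
                           fit_range: tuple[float, float] | None = None
                           ) -> tuple[float, float]:
    """Inflection and maximal-negative-curvature alpha of the D_eff drop.

    Fits a least-squares polynomial (default degree 4) to ``log10 D_eff``
    over the alpha values where D_eff is available (optionally restricted to
    ``fit_range``), evaluates its derivatives on a dense grid, and returns
    ``(alpha_inflection, alpha_dropoff)``:

    * the inflection is the sign-change root of the curvature nearest the
      steepest descent -- the mid-coexistence point, which overestimates the
      transition;
    * the drop-off is the curvature minimum inside the margin-trimmed data
      range -- the end of the purely disordered branch, which always
      precedes the inflection.  The trim (default 10% of the span on each
      side) keeps endpoint oscillations of the global polynomial from
      masquerading as a transition.

    Raises ``ValueError('no transition in range ...')`` when the fitted
    curvature never changes sign or is essentially flat (e.g. linear data).
    """
    if not 3 <= degree <= 6:
        raise ValueError("polynomial degree must be in 3..6")
    sel = scan["d_eff"].notna()
    a = scan.loc[sel, "alpha"].to_numpy(dtype=float)
    d = scan.loc[sel, "d_eff"].to_numpy(dtype=float)
    if fit_range is not None:
        keep = (a >= fit_range[0]) & (a <= fit_range[1])
        a, d = a[keep], d[keep]
    if len(a) < 5:
        raise ValueError("need at least 5 alpha points with D_eff")
    if np.any(d <= 0):
        raise ValueError("non-positive D_eff values")
    coef = np.polyfit(a, np.log10(d), degree)
    grid = np.arange(a.min(), a.max() + grid_step / 2, grid_step)
    d1 = np.polyval(np.polyder(coef, 1), grid)
    d2 = np.polyval(np.polyder(coef, 2), grid)
    if np.ptp(d2) < 1e-9 * max(1.0, np.abs(np.log10(d)).max()):
        raise ValueError("no transition in range (curvature essentially flat)")

    trim = margin * (grid[-1] - grid[0])
    inner = (grid >= grid[0] + trim) & (grid <= grid[-1] - trim)
    k_min = int(np.argmin(np.where(inner, d2, np.inf)))
    if d2[k_min] >= 0:
        raise ValueError("no transition in range (no negative curvature)")
    alpha_dropoff = float(grid[k_min])

    flips = np.nonzero(np.diff(np.sign(d2)) != 0)[0]
    if flips.size == 0:
        raise ValueError("no transition in range (curvature does not change sign)")
    roots = grid[flips] - d2[flips] * grid_step / (d2[flips + 1] - d2[flips])
    steepest = grid[int(np.argmin(d1))]
    alpha_inflection = float(roots[np.argmin(np.abs(roots - steepest))])
    return alpha_inflection, alpha_dropoff


def _bracket_zero(alpha: np.ndarray, g: np.ndarray, what: str) -> float:
    """alpha of the first zero of g, exact on-grid or linearly interpolated."""
    exact = np.nonzero(g == 0)[0]
    if exact.size:
        return float(alpha[exact[0]])
    s = np.sign(g)
    flips = np.nonzero(np.diff(s) != 0)[0]
    if flips.size == 0:
        raise ValueError(f"no {what} crossing inside the scanned alpha range")
    k = flips[0]
    return float(alpha[k] - g[k] * (alpha[k + 1] - alpha[k]) / (g[k + 1] - g[k]))


def crossover_alpha(scan: pd.DataFrame) -> float:
    """alpha at which f6/f5 = 1, by linear interpolation of log(f6/f5)."""
    sel = (scan["f5"] > 0) & (scan["f6"] > 0)
    if sel.sum() < 2:
        raise ValueError("f6/f5 ratio defined on fewer than 2 alpha points")
    a = scan.loc[sel, "alpha"].to_numpy(dtype=float)
    r = np.log(scan.loc[sel, "f6"].to_numpy() / scan.loc[sel, "f5"].to_numpy())
    return _bracket_zero(a, r, "f6/f5 = 1")


def mode_C5_indicator(scan: pd.DataFrame) -> float:
    """alpha at which mode(C_V) crosses the regular-pentagon circularity C(5)."""
    sel = scan["mode_cv"].notna()
    if sel.sum() < 2:
        raise ValueError("mode(C_V) available on fewer than 2 alpha points")
    a = scan.loc[sel, "alpha"].to_numpy(dtype=float)
    g = scan.loc[sel, "mode_cv"].to_numpy(dtype=float) - C5
    return _bracket_zero(a, g, "mode(C_V) = C(5)")
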