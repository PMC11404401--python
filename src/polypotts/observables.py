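"""Dynamic characterization: mean-squared displacement and hexatic order.

MSD uses a single time origin at the end of equilibration,
``<r^2(t)> = <(r(t + t_w) - r(t_w))^2>``, averaged over cells; the long-time
power law ``<r^2> ~ t^beta`` is fitted in log-log space and the effective
diffusion coefficient follows from ``<r^2> = 4 D_eff t`` whenever the
dynamics is actually diffusive (the beta gate).

The local hexatic bond-orientational order of cell k is
``psi6(k) = (1/6) * sum_j exp(6 i theta(j,k))`` over the six nearest cell
centers under the minimum image; |psi6| = 1 for a perfect hexagonal packing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .polylattice import PeriodicBox
from .cpm_engine import Trajectory, cell_cms  # re-exported convenience

__all__ = ["MsdResult", "HexaticResult", "msd", "fit_beta_Deff", "psi6",
           "psi6_trajectory", "cell_cms"]


@dataclass
class MsdResult:
    """Lag table plus (optional) power-law fit results."""

    lag: np.ndarray            # sweeps since the origin (first entry 0)
    msd: np.ndarray
    sem: np.ndarray            # SEM over cells
    beta: float | None = None
    beta_err: float | None = None
    d_eff: float | None = None
    fit_window: tuple[float, float] | None = None


@dataclass
class HexaticResult:
    psi: np.ndarray            # per-cell complex psi6
    abs_psi: np.ndarray
    mean_abs: float
    sem: float


def msd(trajectory: Trajectory, origin: int | None = None,
        multi_origin: bool = False) -> MsdResult:
    """Mean-squared displacement over cells.

    By default a single time origin is used -- ``origin`` is a sample time
    (in sweeps), defaulting to the first sample, which the run protocol
    places at t_w.  With ``multi_origin=True`` every sample acts as an
    origin and displacements are averaged over origins as well; this
    drastically reduces the estimator variance of short reduced-size runs
    (collective fluctuations correlate all cells of a run) at the price of
    correlated lags, and is kept off when reproducing single-origin curves.
    """
    times = trajectory.times
    if origin is None:
        k0 = 0
    else:
        hits = np.nonzero(times == origin)[0]
        if hits.size == 0:
            raise ValueError(f"origin {origin} not among sample times")
        k0 = int(hits[0])
    if len(times) - k0 < 2:
        raise ValueError("need at least 2 samples after the origin")
    pos = trajectory.positions[k0:]
    n_cells = pos.shape[1]
    lags = (times[k0:] - times[k0]).astype(float)
    if multi_origin:
        T = len(pos)
        m = np.empty(T)
        sem = np.empty(T)
        for k in range(T):
            d2 = ((pos[k:] - pos[:T - k]) ** 2).sum(axis=2)  # (origins, cells)
            per_cell = d2.mean(axis=0)
            m[k] = per_cell.mean()
            sem[k] = per_cell.std(ddof=1) / np.sqrt(n_cells)
        return MsdResult(lag=lags, msd=m, sem=sem)
    disp2 = ((pos - pos[0]) ** 2).sum(axis=2)       # (T, n_cells)
    return MsdResult(
        lag=lags,
        msd=disp2.mean(axis=1),
        sem=disp2.std(axis=1, ddof=1) / np.sqrt(n_cells),
    )


def fit_beta_Deff(msd_result: MsdResult,
                  fit_window: tuple[float, float] | None = None,
                  beta_gate: float = 0.05) -> MsdResult:
    """Fit ``beta`` on log-log axes and gate the diffusion coefficient.

    The window defaults to the last decade of lag times.  ``D_eff`` is the
    window mean of ``msd / (4 t)`` and is reported only when
    ``|beta - 1| <= max(beta_gate, SEM(beta))`` -- i.e. the long-time
    dynamics is diffusive within error.  Returns a new ``MsdResult`` with
    the fit fields populated.
    """
    lag, m = msd_result.lag, msd_result.msd
    if fit_window is None:
        t_max = lag.max()
        fit_window = (t_max / 10.0, t_max)
    lo, hi = fit_window
    sel = (lag >= lo) & (lag <= hi) & (lag > 0)
    if sel.sum() < 5:
        raise ValueError("fit window must contain at least 5 positive lags")
    if np.any(m[sel] <= 0):
        raise ValueError("non-positive MSD values inside the fit window")
    x = np.log10(lag[sel])
    y = np.log10(m[sel])
    n = len(x)
    (beta, intercept), cov = np.polyfit(x, y, 1, cov=True)
    beta_err = float(np.sqrt(cov[0, 0]))
    d_eff = None
    if abs(beta - 1.0) <= max(beta_gate, beta_err):
        d_eff = float((m[sel] / (4.0 * lag[sel])).mean())
    return MsdResult(lag=lag, msd=m, sem=msd_result.sem, beta=float(beta),
                     beta_err=beta_err, d_eff=d_eff, fit_window=(lo, hi))


def psi6(centers: np.ndarray, box: PeriodicBox) -> HexaticResult:
    """Hexatic order of a set of cell centers (six nearest neighbors each).

    Neighbor ties at equal distance are broken by cell id, so the result is
    deterministic even on symmetric (e.g. square-grid) arrangements.
    """
    pts = box.wrap(np.asarray(centers, dtype=float))
    n = len(pts)
    if n < 7:
        raise ValueError("psi6 needs at least 7 cells (6 neighbors + self)")
    disp = box.min_image(pts[None, :, :] - pts[:, None, :])   # k -> j
    d2 = (disp ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    # lexicographic (distance, id) order; argsort is stable over the id axis
    nbr = np.argsort(d2, axis=1, kind="stable")[:, :6]
    theta = np.arctan2(
        np.take_along_axis(disp[:, :, 1], nbr, axis=1),
        np.take_along_axis(disp[:, :, 0], nbr, axis=1))
    psi = np.exp(6j * theta).mean(axis=1)
    a = np.abs(psi)
    return HexaticResult(psi=psi, abs_psi=a, mean_abs=float(a.mean()),
                         sem=float(a.std(ddof=1) / np.sqrt(n)))


def psi6_trajectory(trajectory: Trajectory) -> tuple[float, float]:
    """``<|psi6|>`` averaged over cells and samples, with SEM over samples."""
    per_sample = np.array([
        psi6(p, trajectory.box).mean_abs for p in trajectory.positions])
    sem = (per_sample.std(ddof=1) / np.sqrt(len(per_sample))
           if len(per_sample) > 1 else 0.0)
    return float(per_sample.mean()), float(sem)
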