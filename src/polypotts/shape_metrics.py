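"""Voronoi-based cell-shape metrics.

Lattice-based cell borders are jagged (staircase metric), so the perimeter
of a Potts cell is not directly comparable with off-lattice models.  Shapes
are therefore measured on the periodic Voronoi tessellation of the cell
centers of mass, in line with how vertex/Voronoi models define cells.

Quantities
----------
* isoperimetric quotient  q = sqrt(4 pi A) / P     (1 for a disk)
* regular-polygon reference  q_reg(n)  for real n >= 3, and its inverse,
  the generalized edge number  n*(q)
* circularity  C = A^2 / (2 pi tr(I))  with I the centroidal second-moment
  (area) tensor -- a perimeter-free roundness measure (1 for a disk), one of
  the Hu moment invariants
* its regular-polygon reference  C_reg(n)  and inverse  n_circ(C)
* pseudo-polygon fractions f_n: the fraction of cells with n* in
  (n - 1/2, n + 1/2]

Note the classical quotient ``4 pi A / P^2`` equals ``q**2`` here; it is
exposed as :func:`iso_quotient_classic` for comparison with other work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .polylattice import PeriodicBox, build_voronoi

__all__ = [
    "voronoi_shapes", "shape_table", "iso_quotient", "iso_quotient_classic",
    "q_reg", "n_star", "polygon_moment_trace", "circularity", "c_reg",
    "n_circ", "C5", "pseudo_fractions", "DistributionSummary",
    "distribution_summary",
]


# ---------------------------------------------------------------------------
# elementary shape functionals
# ---------------------------------------------------------------------------

def iso_quotient(A: float, P: float) -> float:
    """Isoperimetric quotient q = sqrt(4 pi A) / P (scale-invariant, <= 1)."""
    if A <= 0 or P <= 0:
        raise ValueError("area and perimeter must be positive")
    return float(np.sqrt(4.0 * np.pi * A) / P)


def iso_quotient_classic(A: float, P: float) -> float:
    """The classical dimensionless ratio 4 pi A / P^2 (= q squared)."""
    return iso_quotient(A, P) ** 2


def q_reg(n) -> float | np.ndarray:
    """Isoperimetric quotient of a regular n-gon; n may be real (>= 3).

    With circumradius r: A = (n/2) r^2 sin(2 pi / n) and
    P = 2 n r sin(pi / n), so q is independent of r, strictly increasing in
    n, and tends to 1 (the disk) as n -> infinity.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 3):
        raise ValueError("q_reg requires n >= 3")
    q = np.sqrt(2.0 * np.pi * n * np.sin(2.0 * np.pi / n)) \
        / (2.0 * n * np.sin(np.pi / n))
    return float(q) if q.ndim == 0 else q


def c_reg(n) -> float | np.ndarray:
    """Circularity of a regular n-gon (real n >= 3), from closed-form moments.

    C_reg(n) = 3 n sin(2 pi/n) / (2 pi (2 + cos(2 pi/n))); C_reg(4) = 3/pi
    and the disk limit is 1.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 3):
        raise ValueError("c_reg requires n >= 3")
    x = 2.0 * np.pi / n
    c = 3.0 * n * np.sin(x) / (2.0 * np.pi * (2.0 + np.cos(x)))
    return float(c) if c.ndim == 0 else c


#: circularity of the regular pentagon -- the transition indicator reference
C5: float = float(c_reg(5.0))

_Q3 = None
_C3 = None


def _invert(fn, value, name: str, clamp_warn: str):
    lo = fn(3.0)
    if value >= 1.0:
        raise ValueError(f"{name} must be < 1 (disk limit)")
    if value <= lo:
        if value < lo:
            warnings.warn(clamp_warn, stacklevel=3)
        return 3.0
    hi = 6.0
    while fn(hi) < value:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError(f"failed to bracket {name} = {value}")
    return float(brentq(lambda n: fn(n) - value, 3.0, hi, xtol=1e-13, rtol=8.9e-16))


def n_star(q: float) -> float:
    """Generalized edge number: the unique n* >= 3 with q_reg(n*) = q.

    Values below q_reg(3) clamp to 3 with a warning; q >= 1 is an error.
    """
    return _invert(q_reg, float(q), "q",
                   "q below the triangle value q_reg(3); n* clamped to 3")


def n_circ(C: float) -> float:
    """Circularity-derived edge number: inverse of C_reg (same conventions)."""
    return _invert(c_reg, float(C), "C",
                   "C below the triangle value C_reg(3); n_circ clamped to 3")


# ---------------------------------------------------------------------------
# polygon moments and circularity
# ---------------------------------------------------------------------------

def polygon_moment_trace(vertices: np.ndarray) -> tuple[float, float]:
    """(area, trace of the centroidal second-moment-of-area tensor).

    Closed-form shoelace second moments: with the polygon translated to its
    centroid and cross_i = x_i y_{i+1} - x_{i+1} y_i,

        Ixx = (1/12) sum_i cross_i (y_i^2 + y_i y_{i+1} + y_{i+1}^2)
        Iyy = (1/12) sum_i cross_i (x_i^2 + x_i x_{i+1} + x_{i+1}^2)
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("vertices must be an (m >= 3, 2) ring")
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ValueError("degenerate polygon (zero area)")
    if area < 0:                       # enforce CCW orientation
        return polygon_moment_trace(v[::-1])
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    x, y = x - cx, y - cy
    xn, yn = xn - cx, yn - cy
    cross = x * yn - xn * y
    ixx = (cross * (y * y + y * yn + yn * yn)).sum() / 12.0
    iyy = (cross * (x * x + x * xn + xn * xn)).sum() / 12.0
    return float(area), float(ixx + iyy)


def circularity(vertices: np.ndarray) -> float:
    """C = A^2 / (2 pi tr(I)); 1 for a disk, invariant under similarity."""
    area, tr = polygon_moment_trace(vertices)
    return float(area * area / (2.0 * np.pi * tr))


# ---------------------------------------------------------------------------
# Voronoi shape pipeline
# ---------------------------------------------------------------------------

def voronoi_shapes(centers: np.ndarray, box: PeriodicBox):
    """Periodic Voronoi polygons of the cell centers with areas/perimeters.

    Returns ``(polygons, areas, perimeters)`` where ``polygons`` is a list of
    vertex rings in input order.  The tessellation covers the box exactly.
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) < 4:
        raise ValueError("need at least 4 centers")
    lat = build_voronoi(centers, box)   # self-image contact -> rejected
    polys = [s.vertices for s in lat.sites]
    areas = lat.site_areas
    perims = np.array([np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1).sum()
                       for v in polys])
    return polys, areas, perims


def shape_table(centers: np.ndarray, box: PeriodicBox, *,
                with_n_circ: bool = False) -> pd.DataFrame:
    """Per-cell shape metrics as a tidy DataFrame (cell, A, P, q_v, n_star, C_v)."""
    polys, areas, perims = voronoi_shapes(centers, box)
    qv = np.array([iso_quotient(a, p) for a, p in zip(areas, perims)])
    rows = {
        "cell": np.arange(1, len(polys) + 1),
        "A": areas,
        "P": perims,
        "q_v": qv,
        "n_star": np.array([n_star(q) for q in qv]),
        "C_v": np.array([circularity(v) for v in polys]),
    }
    if with_n_circ:
        rows["n_circ"] = np.array([n_circ(c) for c in rows["C_v"]])
    return pd.DataFrame(rows)


def pseudo_fractions(n_star_values) -> pd.DataFrame:
    """Fractions f_n of pseudo-n-gons, binned by n - 1/2 < n* <= n + 1/2.

    The upper edge is inclusive (a cell with n* = 5.5 is a pseudo-pentagon).
    Fractions are reported for n = 3..9 and sum to 1; out-of-range values
    are clipped into the end bins.
    """
    v = np.asarray(list(n_star_values), dtype=float)
    if v.size == 0:
        raise ValueError("empty n* list")
    n = np.ceil(v - 0.5).astype(int)
    n = np.clip(n, 3, 9)
    counts = np.bincount(n, minlength=10)[3:10]
    return pd.DataFrame({"n": np.arange(3, 10), "fraction": counts / v.size})


# ---------------------------------------------------------------------------
# histogram mode / minimum extraction
# ---------------------------------------------------------------------------

@dataclass
class DistributionSummary:
    """Density-normalized histogram with fitted extrema.

    ``peaks`` holds one (unimodal) or two (bimodal) refined peak positions;
    ``minimum`` is the interior local minimum between two peaks, else None.
    """

    bin_centers: np.ndarray
    density: np.ndarray
    sem: np.ndarray
    peaks: list
    peak_heights: list
    minimum: float | None
    bimodal: bool


def _parabola_vertex(xc: np.ndarray, yc: np.ndarray, idx: int, half: int) -> float:
    lo = max(0, idx - half)
    hi = min(len(xc), idx + half + 1)
    xs, ys = xc[lo:hi], yc[lo:hi]
    if len(xs) < 3:
        return float(xc[idx])
    a, b, _ = np.polyfit(xs, ys, 2)
    if a == 0:
        return float(xc[idx])
    v = -b / (2.0 * a)
    # keep the vertex inside the fit range; otherwise fall back to the bin
    if xs[0] <= v <= xs[-1]:
        return float(v)
    return float(xc[idx])


def distribution_summary(values, n_bins: int = 60, fit_halfwidth: int = 3,
                         min_rel_height: float = 0.05) -> DistributionSummary:
    """Histogram a sample and locate its mode(s) by local quadratic fits.

    Bimodality requires two separated local maxima, the smaller at least
    ``min_rel_height`` of the larger (rejects Poisson noise bumps in thin
    tails), whose heights each exceed the interior valley by more than twice
    the combined bin SEM (a persistence threshold against counting noise);
    the refined interior minimum is then reported as well.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 100:
        raise ValueError("need at least 100 values for a distribution summary")
    if np.ptp(v) == 0:                 # degenerate: all values identical
        x = float(v[0])
        return DistributionSummary(np.array([x]), np.array([np.inf]),
                                   np.array([0.0]), [x], [np.inf], None, False)
    counts, edges = np.histogram(v, bins=n_bins)
    bw = edges[1] - edges[0]
    density = counts / (v.size * bw)
    sem = np.sqrt(counts) / (v.size * bw)
    xc = 0.5 * (edges[:-1] + edges[1:])

    # interior local maxima (plateaus count once, leftmost bin)
    cand = []
    for i in range(len(density)):
        left = density[i - 1] if i > 0 else -np.inf
        right = density[i + 1] if i < len(density) - 1 else -np.inf
        if density[i] > left and density[i] >= right and density[i] > 0:
            cand.append(i)
    if not cand:
        cand = [int(np.argmax(density))]
    cand.sort(key=lambda i: -density[i])
    main = cand[0]

    bimodal = False
    second = None
    valley = None
    for i in cand[1:]:
        if density[i] < min_rel_height * density[main]:
            continue
        lo, hi = sorted((main, i))
        if hi - lo < 2:
            continue
        k = lo + 1 + int(np.argmin(density[lo + 1:hi]))
        depth = min(density[main], density[i]) - density[k]
        if depth > 2.0 * np.hypot(sem[k], sem[i]):
            bimodal = True
            second, valley = i, k
            break

    peaks = [_parabola_vertex(xc, density, main, fit_halfwidth)]
    heights = [float(density[main])]
    minimum = None
    if bimodal:
        peaks.append(_parabola_vertex(xc, density, second, fit_halfwidth))
        heights.append(float(density[second]))
        order = np.argsort(peaks)
        peaks = [peaks[k] for k in order]
        heights = [heights[k] for k in order]
        minimum = _parabola_vertex(xc, density, valley, fit_halfwidth)
    return DistributionSummary(xc, density, sem, peaks, heights, minimum, bimodal)
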