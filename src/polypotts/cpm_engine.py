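"""Metropolis Monte-Carlo dynamics of the cellular Potts model on a PolyLattice.

The configuration is a spin field sigma mapping each lattice site to a cell
index (confluent: every site belongs to exactly one cell).  The Hamiltonian is

    H = alpha * sum_{<i,j>} w_ij * [sigma(i) != sigma(j)]
        + lam * sum_c (a_c - A0)^2

with the adjacency sum over distinct site pairs (each unordered pair counted
once), ``w_ij`` the edge-length weight supplied by the lattice (1 on regular
lattices), ``a_c`` the instantaneous cell area, and ``A0`` the target area.

An elementary attempt picks a candidate site uniformly, an invading site
uniformly from its full neighbor list, and copies the invader's spin with the
Metropolis probability ``min(1, exp(-dE/kT))``.  Same-spin picks are no-ops
but still consume an attempt, which defines the Monte-Carlo-sweep clock:
one sweep = N_s attempts.

The hot loop is JIT-compiled (numba) over flat CSR adjacency arrays; all
randomness comes from a single explicit xorshift128+ stream per run, so runs
are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from numba import njit
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .polylattice import PeriodicBox, PolyLattice

__all__ = [
    "SimParams",
    "SpinField",
    "EnergyBreakdown",
    "CpmRng",
    "Trajectory",
    "total_energy",
    "delta_energy",
    "attempt",
    "sweep",
    "run_sweeps",
    "init_rectangles",
    "init_hexagonal_cells",
    "run",
    "fragmentation_report",
    "cell_cms",
]

_MASK64 = (1 << 64) - 1


# ---------------------------------------------------------------------------
# random numbers: xorshift128+ with splitmix64 seeding
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return s0 + s1


@njit(cache=True, inline="always")
def _next_double(state):
    # 53 random mantissa bits -> uniform in [0, 1)
    return (_next_u64(state) >> np.uint64(11)) * 1.1102230246251565e-16


@njit(cache=True, inline="always")
def _randbelow(state, n):
    """Unbiased integer in [0, n) by rejection sampling."""
    nn = np.uint64(n)
    lim = (np.uint64(0xFFFFFFFFFFFFFFFF) // nn) * nn
    x = _next_u64(state)
    while x >= lim:
        x = _next_u64(state)
    return np.int64(x % nn)


@njit(cache=True, inline="always")
def _metropolis(dE, kT, state):
    """The acceptance rule: always for dE <= 0, else with prob exp(-dE/kT)."""
    if dE <= 0.0:
        return True
    return _next_double(state) < np.exp(-dE / kT)


class CpmRng:
    """The single random stream of a run (xorshift128+, splitmix64-seeded)."""

    def __init__(self, seed: int):
        z = int(seed) & _MASK64
        state = []
        for _ in range(2):
            z = (z + 0x9E3779B97F4A7C15) & _MASK64
            t = z
            t = ((t ^ (t >> 30)) * 0xBF58476D1CE4E91D) & _MASK64
            t = ((t ^ (t >> 27)) * 0x94D049BB133111EB) & _MASK64
            state.append(t ^ (t >> 31))
        if state[0] == 0 and state[1] == 0:
            state[1] = 1
        self.state = np.array(state, dtype=np.uint64)

    def random(self) -> float:
        return float(_next_double(self.state))


# ---------------------------------------------------------------------------
# parameters and configuration
# ---------------------------------------------------------------------------

@dataclass
class SimParams:
    """Physical parameters and run protocol.

    alpha : surface tension (energy per unit contact weight), the control
        parameter of the fluid--solid scan.
    lam : area-spring strength (energy / area^2).
    A0 : target cell area.
    kT : thermal energy scale of the Metropolis rule.
    t_w, t_s : equilibration (waiting) and sampling sweeps.
    sample_every : sweeps between trajectory samples.
    neighbor_pick : "uniform" picks the invading site uniformly from the
        neighbor list; "length_weighted" picks proportionally to the shared
        edge length (sensitivity switch; uniform is the default).
    """

    alpha: float
    lam: float = 1.0
    A0: float = 40.0
    kT: float = 1.0
    seed: int = 0
    t_w: int = 0
    t_s: int = 0
    sample_every: int = 1
    neighbor_pick: str = "uniform"

    def __post_init__(self) -> None:
        if min(self.alpha, self.lam, self.A0, self.kT) <= 0:
            raise ValueError("alpha, lam, A0 and kT must be positive")
        if self.t_w < 0 or self.t_s < 0 or self.sample_every < 1:
            raise ValueError("t_w, t_s must be >= 0 and sample_every >= 1")
        if self.neighbor_pick not in ("uniform", "length_weighted"):
            raise ValueError("neighbor_pick must be 'uniform' or 'length_weighted'")

    @property
    def pick_mode(self) -> int:
        return 0 if self.neighbor_pick == "uniform" else 1


class SpinField:
    """Cell configuration: site -> cell map plus incremental per-cell areas.

    Cell ids run 1..n_cells; ``cell_area[c]`` is the running area of cell c
    (index 0 unused).
    """

    def __init__(self, spin: np.ndarray, n_cells: int, lattice: PolyLattice):
        spin = np.asarray(spin, dtype=np.int64)
        if spin.shape != (lattice.n_sites,):
            raise ValueError("spin must assign exactly one cell per site")
        if spin.min() < 1 or spin.max() > n_cells:
            raise ValueError("spin values must lie in [1, n_cells]")
        self.spin = spin
        self.n_cells = int(n_cells)
        self.cell_area = self.recomputed_areas(lattice)

    def recomputed_areas(self, lattice: PolyLattice) -> np.ndarray:
        return np.bincount(self.spin, weights=lattice.site_areas,
                           minlength=self.n_cells + 1)

    def refresh_areas(self, lattice: PolyLattice) -> None:
        self.cell_area = self.recomputed_areas(lattice)

    def copy(self) -> "SpinField":
        out = object.__new__(SpinField)
        out.spin = self.spin.copy()
        out.n_cells = self.n_cells
        out.cell_area = self.cell_area.copy()
        return out


@dataclass(frozen=True)
class EnergyBreakdown:
    surface: float
    area: float

    @property
    def total(self) -> float:
        return self.surface + self.area


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def total_energy(lattice: PolyLattice, field: SpinField,
                 params: SimParams) -> EnergyBreakdown:
    """Full Hamiltonian, each unordered adjacency pair counted once."""
    indptr, indices, weights, _ = lattice.adjacency_csr()
    spin = field.spin
    rows = np.repeat(np.arange(lattice.n_sites), np.diff(indptr))
    once = rows < indices
    unlike = spin[rows] != spin[indices]
    surface = params.alpha * weights[once & unlike].sum()
    area = params.lam * ((field.cell_area[1:] - params.A0) ** 2).sum()
    return EnergyBreakdown(surface=float(surface), area=float(area))


@njit(cache=True)
def _delta_energy(indptr, indices, weights, site_area, spin, cell_area,
                  alpha, lam, A0, i, s_new):
    s_old = spin[i]
    dsurf = 0.0
    for k in range(indptr[i], indptr[i + 1]):
        sj = spin[indices[k]]
        w = weights[k]
        if sj != s_new:
            dsurf += w
        if sj != s_old:
            dsurf -= w
    ai = site_area[i]
    a_old = cell_area[s_old]
    a_new = cell_area[s_new]
    darea = ((a_new + ai - A0) ** 2 + (a_old - ai - A0) ** 2
             - (a_new - A0) ** 2 - (a_old - A0) ** 2)
    return alpha * dsurf + lam * darea


def delta_energy(lattice: PolyLattice, field: SpinField, params: SimParams,
                 site: int, new_spin: int) -> float:
    """Energy change of retyping ``site`` to ``new_spin``; local computation.

    Exactly equals ``total_energy(after) - total_energy(before)``; this is
    the engine's core contract and is property-tested against the full sum.
    """
    if not 0 <= site < lattice.n_sites:
        raise ValueError(f"site {site} outside lattice")
    if not 1 <= new_spin <= field.n_cells:
        raise ValueError(f"unknown cell id {new_spin}")
    if new_spin == field.spin[site]:
        raise ValueError("new_spin equals the current spin (same-spin no-op)")
    indptr, indices, weights, _ = lattice.adjacency_csr()
    return float(_delta_energy(indptr, indices, weights, lattice.site_areas,
                               field.spin, field.cell_area, params.alpha,
                               params.lam, params.A0, site, new_spin))


# ---------------------------------------------------------------------------
# the Monte-Carlo kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _attempts(indptr, indices, weights, elens, site_area, spin, cell_area,
              alpha, lam, A0, kT, n_attempts, state, pick_mode):
    n_sites = spin.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        i = _randbelow(state, n_sites)
        lo = indptr[i]
        hi = indptr[i + 1]
        if pick_mode == 0:
            j = indices[lo + _randbelow(state, hi - lo)]
        else:
            tot = 0.0
            for k in range(lo, hi):
                tot += elens[k]
            u = _next_double(state) * tot
            j = indices[hi - 1]
            acc = 0.0
            for k in range(lo, hi):
                acc += elens[k]
                if u < acc:
                    j = indices[k]
                    break
        s_new = spin[j]
        s_old = spin[i]
        if s_new == s_old:
            continue  # same-spin pick: disregarded, but consumes the attempt
        dsurf = 0.0
        for k in range(lo, hi):
            sj = spin[indices[k]]
            w = weights[k]
            if sj != s_new:
                dsurf += w
            if sj != s_old:
                dsurf -= w
        ai = site_area[i]
        a_old = cell_area[s_old]
        a_new = cell_area[s_new]
        darea = ((a_new + ai - A0) ** 2 + (a_old - ai - A0) ** 2
                 - (a_new - A0) ** 2 - (a_old - A0) ** 2)
        dE = alpha * dsurf + lam * darea
        if _metropolis(dE, kT, state):
            spin[i] = s_new
            cell_area[s_old] = a_old - ai
            cell_area[s_new] = a_new + ai
            accepted += 1
    return accepted


def _kernel_args(lattice: PolyLattice, field: SpinField, params: SimParams):
    indptr, indices, weights, elens = lattice.adjacency_csr()
    return (indptr, indices, weights, elens, lattice.site_areas, field.spin,
            field.cell_area, params.alpha, params.lam, params.A0, params.kT)


def attempt(lattice: PolyLattice, field: SpinField, params: SimParams,
            rng: CpmRng) -> bool:
    """One elementary copy attempt; mutates ``field`` in place on acceptance."""
    args = _kernel_args(lattice, field, params)
    return bool(_attempts(*args, 1, rng.state, params.pick_mode))


def sweep(lattice: PolyLattice, field: SpinField, params: SimParams,
          rng: CpmRng) -> int:
    """Exactly N_s attempts; returns the number accepted."""
    args = _kernel_args(lattice, field, params)
    return int(_attempts(*args, lattice.n_sites, rng.state, params.pick_mode))


def run_sweeps(lattice: PolyLattice, field: SpinField, params: SimParams,
               rng: CpmRng, n_sweeps: int) -> int:
    """``n_sweeps`` back-to-back sweeps inside the kernel; returns accepted count."""
    if n_sweeps <= 0:
        return 0
    args = _kernel_args(lattice, field, params)
    return int(_attempts(*args, n_sweeps * lattice.n_sites, rng.state,
                         params.pick_mode))


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def init_rectangles(lattice: PolyLattice, cell_w: float, cell_h: float) -> SpinField:
    """Tile the box with ~cell_w x cell_h rectangles; one cell per rectangle.

    Rectangle widths are stretched so an integer number fits exactly; each
    site joins the rectangle containing its centroid, empty rectangles are
    dropped and cells renumbered densely.
    """
    box = lattice.box
    nx = max(1, round(box.Lx / cell_w))
    ny = max(1, round(box.Ly / cell_h))
    w, h = box.Lx / nx, box.Ly / ny
    cen = box.wrap(lattice.centroids)
    col = np.minimum((cen[:, 0] / w).astype(np.int64), nx - 1)
    row = np.minimum((cen[:, 1] / h).astype(np.int64), ny - 1)
    raw = col * ny + row
    _, spin = np.unique(raw, return_inverse=True)
    field = SpinField(spin + 1, int(spin.max()) + 1, lattice)
    if field.n_cells < 2:
        raise ValueError("rectangle tiling produced fewer than 2 cells")
    return field


def hexagon_grid(box: PeriodicBox, A0: float,
                 max_distortion: float = 0.02) -> np.ndarray:
    """Centers of a periodic hexagonal tiling of ``box`` with cell area ~A0.

    Raises if the box cannot accommodate hexagons of area A0 within the
    allowed linear distortion, suggesting the nearest tileable dimensions.
    """
    R0 = math.sqrt(A0 / (1.5 * math.sqrt(3.0)))
    w0, p0 = math.sqrt(3.0) * R0, 1.5 * R0
    n_cols = max(1, round(box.Lx / w0))
    n_rows = max(2, 2 * round(box.Ly / (2 * p0)))
    wx, py = box.Lx / n_cols, box.Ly / n_rows
    if abs(wx / w0 - 1) > max_distortion or abs(py / p0 - 1) > max_distortion:
        raise ValueError(
            f"box ({box.Lx:.4g} x {box.Ly:.4g}) not tileable by hexagons of "
            f"area {A0:g} within {max_distortion:.0%} distortion; nearest "
            f"tileable box is {n_cols * w0:.4g} x {n_rows * p0:.4g}")
    centers = np.array([[(c + 0.5 * (r % 2)) * wx, (r + 0.5) * py]
                        for r in range(n_rows) for c in range(n_cols)])
    return centers


def init_hexagonal_cells(lattice: PolyLattice, A0: float) -> SpinField:
    """Crystalline start: assign sites to the nearest hexagon-tiling center.

    Used to initialize high-surface-tension (solid) runs; the resulting cell
    centers carry near-perfect hexatic order before any dynamics.
    """
    centers = hexagon_grid(lattice.box, A0)
    cen = lattice.centroids
    box = lattice.box
    spin = np.empty(lattice.n_sites, dtype=np.int64)
    chunk = 4096
    for a in range(0, lattice.n_sites, chunk):
        d = box.min_image(cen[a:a + chunk, None, :] - centers[None, :, :])
        spin[a:a + chunk] = np.argmin((d ** 2).sum(axis=2), axis=1)
    _, spin = np.unique(spin, return_inverse=True)
    field = SpinField(spin + 1, int(spin.max()) + 1, lattice)
    if field.n_cells < 2:
        raise ValueError("hexagonal tiling produced fewer than 2 cells")
    return field


# ---------------------------------------------------------------------------
# observation plumbing
# ---------------------------------------------------------------------------

def cell_cms(lattice: PolyLattice, field: SpinField,
             prev_positions: np.ndarray | None = None) -> np.ndarray:
    """Periodic-aware, area-weighted center of mass of every cell.

    Member-site displacements are taken minimum-image relative to a reference
    per cell -- the previous CMS when given (keeps trajectories continuous,
    i.e. unwrapped, across box crossings), else the centroid of the cell's
    first site.
    """
    nc = field.n_cells
    areas = field.recomputed_areas(lattice)[1:]
    if np.any(areas <= 0):
        empty = np.nonzero(areas <= 0)[0] + 1
        raise ValueError(f"empty cell(s): {empty.tolist()}")
    cen = lattice.centroids
    spin = field.spin
    if prev_positions is None:
        ref = np.empty((nc, 2))
        rev = np.arange(lattice.n_sites)[::-1]
        first = np.empty(nc + 1, dtype=np.int64)
        first[spin[rev]] = rev
        ref[:] = cen[first[1:]]
    else:
        ref = np.asarray(prev_positions, dtype=float)
        if ref.shape != (nc, 2):
            raise ValueError("prev_positions must be (n_cells, 2)")
    disp = lattice.box.min_image(cen - ref[spin - 1])
    w = lattice.site_areas
    sx = np.bincount(spin, weights=w * disp[:, 0], minlength=nc + 1)[1:]
    sy = np.bincount(spin, weights=w * disp[:, 1], minlength=nc + 1)[1:]
    return ref + np.stack([sx, sy], axis=1) / areas[:, None]


@dataclass
class Trajectory:
    """Time series of unwrapped per-cell CMS positions plus state snapshots."""

    times: np.ndarray                 # sample sweeps (absolute, first = t_w)
    positions: np.ndarray             # (n_samples, n_cells, 2), unwrapped
    box: PeriodicBox
    params: SimParams
    acceptance_rate: float
    snapshots: list = dc_field(default_factory=list)  # (sweep, spin-array) pairs

    @property
    def n_samples(self) -> int:
        return len(self.times)


class CellEvaporationError(RuntimeError):
    pass


def run(lattice: PolyLattice, field: SpinField, params: SimParams,
        observers=None, *, snapshot_every: int | None = None,
        strict: bool = True, rng: CpmRng | None = None) -> Trajectory:
    """Execute the full protocol: t_w equilibration then t_s sampling sweeps.

    The CMS is recorded every ``params.sample_every`` sweeps during sampling
    (plus the sample at t_w itself); ``observers`` are callables
    ``f(t, lattice, field, positions)`` invoked at each sample.  Snapshots of
    the full spin field are stored every ``snapshot_every`` samples (always
    the final state).  A cell whose area reaches zero aborts the run in
    strict mode and warns otherwise.
    """
    if rng is None:
        rng = CpmRng(params.seed)
    observers = observers or []

    def check_confluent(t):
        if field.cell_area[1:].min() <= 0:
            msg = f"cell evaporated by sweep {t}"
            if strict:
                raise CellEvaporationError(msg)
            warnings.warn(msg, stacklevel=2)

    accepted = 0
    done = 0
    while done < params.t_w:
        block = min(1000, params.t_w - done)
        accepted += run_sweeps(lattice, field, params, rng, block)
        done += block
        check_confluent(done)

    field.refresh_areas(lattice)
    n_samples = params.t_s // params.sample_every
    times = params.t_w + params.sample_every * np.arange(n_samples + 1)
    positions = np.empty((n_samples + 1, field.n_cells, 2))
    positions[0] = cell_cms(lattice, field)
    snapshots = []
    for obs in observers:
        obs(times[0], lattice, field, positions[0])
    total_attempts = max(1, (params.t_w + n_samples * params.sample_every)
                         * lattice.n_sites)
    for k in range(1, n_samples + 1):
        accepted += run_sweeps(lattice, field, params, rng, params.sample_every)
        check_confluent(times[k])
        field.refresh_areas(lattice)   # shed incremental float drift
        positions[k] = cell_cms(lattice, field, prev_positions=positions[k - 1])
        if snapshot_every and k % snapshot_every == 0:
            snapshots.append((int(times[k]), field.spin.copy()))
        for obs in observers:
            obs(times[k], lattice, field, positions[k])
    if not snapshots or snapshots[-1][0] != times[-1]:
        snapshots.append((int(times[-1]), field.spin.copy()))
    return Trajectory(times=times, positions=positions, box=lattice.box,
                      params=params, acceptance_rate=accepted / total_attempts,
                      snapshots=snapshots)


def fragmentation_report(lattice: PolyLattice, field: SpinField) -> dict[int, int]:
    """Connected components of each cell under positive-length adjacency.

    A count above 1 means the cell has fragmented into disconnected islands;
    used as a passive run-health monitor (no connectivity constraint is
    imposed on the dynamics).
    """
    indptr, indices, _, elens = lattice.adjacency_csr()
    rows = np.repeat(np.arange(lattice.n_sites), np.diff(indptr))
    keep = (elens > 0) & (field.spin[rows] == field.spin[indices])
    g = sparse.coo_matrix(
        (np.ones(keep.sum()), (rows[keep], indices[keep])),
        shape=(lattice.n_sites, lattice.n_sites))
    _, labels = connected_components(g, directed=False)
    out = {}
    for c in range(1, field.n_cells + 1):
        out[c] = len(np.unique(labels[field.spin == c]))
    return out
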