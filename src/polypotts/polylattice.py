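"""Periodic polygonal lattices for the generalized cellular Potts model.

A :class:`PolyLattice` is the static substrate on which the Potts dynamics
runs: a periodic box tiled by simple polygons (the lattice *sites*), with a
symmetric adjacency relation between sites and, for irregular lattices, an
edge-length weight ``w_ij = l_ij / l_bar`` that scales the surface-energy
contribution of each site contact.

Two sites are neighbors iff their polygons share at least one vertex.  On a
square lattice this rule yields the 8-site Moore neighborhood (the four
diagonal contacts share only a corner and carry ``l_ij = 0``); on a hexagonal
lattice it yields the 6 nearest hexagons; on a Voronoi lattice the neighbor
count varies per site.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi, cKDTree

__all__ = [
    "PeriodicBox",
    "LatticeSite",
    "PolyLattice",
    "build_square",
    "build_hexagonal",
    "build_voronoi",
    "save_lattice",
    "load_lattice",
    "LatticeFormatError",
]


class LatticeFormatError(ValueError):
    """Raised when a serialized lattice file violates the format or an invariant."""


@dataclass(frozen=True)
class PeriodicBox:
    """Rectangular periodic domain; all geometry uses the minimum-image convention."""

    Lx: float
    Ly: float

    def __post_init__(self) -> None:
        if not (self.Lx > 0 and self.Ly > 0):
            raise ValueError("box dimensions must be positive")

    @property
    def area(self) -> float:
        return self.Lx * self.Ly

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly])

    def wrap(self, points: np.ndarray) -> np.ndarray:
        """Fold coordinates into [0, Lx) x [0, Ly)."""
        return np.mod(points, self.lengths)

    def min_image(self, disp: np.ndarray) -> np.ndarray:
        """Minimum-image representative of displacement vectors."""
        L = self.lengths
        return disp - L * np.round(disp / L)


@dataclass
class LatticeSite:
    """One polygonal site: geometry plus its (symmetric) neighbor relation.

    ``vertices`` is an unwrapped local copy of the polygon ring (CCW);
    ``edge_lengths[k]`` is the shared-boundary length with ``neighbor_ids[k]``
    (0 for vertex-only contacts).
    """

    id: int
    vertices: np.ndarray
    centroid: np.ndarray
    area: float
    neighbor_ids: np.ndarray
    edge_lengths: np.ndarray


def _polygon_area_centroid(verts: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed shoelace area and centroid of a simple polygon (ring, no repeat)."""
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    if a == 0:
        raise ValueError("degenerate polygon (zero area)")
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return a, np.array([cx, cy])


def _ccw(verts: np.ndarray) -> np.ndarray:
    a, _ = _polygon_area_centroid(verts)
    return verts if a > 0 else verts[::-1]


class PolyLattice:
    """Periodic polygonal lattice: sites, adjacency, edge weights.

    Parameters
    ----------
    box : PeriodicBox
    sites : sequence of LatticeSite
    weight_mode : {"uniform", "edge-weighted"}
        ``uniform`` sets every adjacency weight to 1 (classic regular-lattice
        Hamiltonian); ``edge-weighted`` uses ``w_ij = l_ij / l_bar`` where
        ``l_bar`` is the mean length of all distinct positive-length edges.
    """

    def __init__(self, box: PeriodicBox, sites: Sequence[LatticeSite],
                 weight_mode: str = "uniform", validate: bool = True):
        if weight_mode not in ("uniform", "edge-weighted"):
            raise ValueError(f"unknown weight_mode {weight_mode!r}")
        self.box = box
        self.sites = list(sites)
        self.weight_mode = weight_mode
        self._csr: tuple[np.ndarray, ...] | None = None
        self.mean_edge_length = self._compute_mean_edge_length()
        if validate:
            self.validate()

    # -- derived structure ------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def site_areas(self) -> np.ndarray:
        return np.array([s.area for s in self.sites])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([s.centroid for s in self.sites])

    def _compute_mean_edge_length(self) -> float:
        """Mean over each distinct undirected edge with l > 0, counted once."""
        total = 0.0
        count = 0
        for s in self.sites:
            for j, l in zip(s.neighbor_ids, s.edge_lengths):
                if l > 0 and s.id < j:
                    total += l
                    count += 1
            # self-symmetric pairs never occur (no self-adjacency)
        if count == 0:
            raise ValueError("lattice has no positive-length edges")
        return total / count

    def weight(self, i: int, j: int) -> float:
        s = self.sites[i]
        k = np.nonzero(s.neighbor_ids == j)[0]
        if k.size == 0:
            raise KeyError(f"sites {i} and {j} are not adjacent")
        if self.weight_mode == "uniform":
            return 1.0
        return float(s.edge_lengths[k[0]] / self.mean_edge_length)

    def adjacency_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flattened adjacency: (indptr, indices, weights, edge_lengths).

        ``indices[indptr[i]:indptr[i+1]]`` are the neighbors of site ``i``;
        weights are aligned and follow ``weight_mode``.
        """
        if self._csr is None:
            indptr = np.zeros(self.n_sites + 1, dtype=np.int64)
            for s in self.sites:
                indptr[s.id + 1] = len(s.neighbor_ids)
            np.cumsum(indptr, out=indptr)
            indices = np.empty(indptr[-1], dtype=np.int64)
            lens = np.empty(indptr[-1], dtype=np.float64)
            for s in self.sites:
                indices[indptr[s.id]:indptr[s.id + 1]] = s.neighbor_ids
                lens[indptr[s.id]:indptr[s.id + 1]] = s.edge_lengths
            if self.weight_mode == "uniform":
                weights = np.ones_like(lens)
            else:
                weights = lens / self.mean_edge_length
            self._csr = (indptr, indices, weights, lens)
        return self._csr

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        areas = self.site_areas
        if np.any(areas <= 0):
            raise LatticeFormatError("site with non-positive area")
        total = areas.sum()
        if abs(total - self.box.area) > 1e-8 * self.box.area:
            raise LatticeFormatError(
                f"site areas sum to {total}, box area is {self.box.area}")
        neigh = {s.id: dict(zip(s.neighbor_ids.tolist(), s.edge_lengths.tolist()))
                 for s in self.sites}
        for s in self.sites:
            if s.id in neigh[s.id]:
                raise LatticeFormatError(f"site {s.id} is its own neighbor")
            for j, l in neigh[s.id].items():
                if j not in neigh or s.id not in neigh[j]:
                    raise LatticeFormatError(
                        f"asymmetric adjacency between sites {s.id} and {j}")
                if not math.isclose(l, neigh[j][s.id], rel_tol=1e-9, abs_tol=1e-12):
                    raise LatticeFormatError(
                        f"edge length mismatch between sites {s.id} and {j}")
        if self.weight_mode == "edge-weighted":
            _, _, w, l = self.adjacency_csr()
            pos = l > 0
            # each undirected edge appears twice in CSR; the mean is unaffected
            mean_w = w[pos].mean()
            if abs(mean_w - 1.0) > 1e-8:
                raise LatticeFormatError(f"edge-weight mean {mean_w} != 1")

    def __repr__(self) -> str:
        return (f"PolyLattice(n_sites={self.n_sites}, box=({self.box.Lx:g}, "
                f"{self.box.Ly:g}), weight_mode={self.weight_mode!r})")


# ---------------------------------------------------------------------------
# regular builders
# ---------------------------------------------------------------------------

def build_square(n_cols: int, n_rows: int, spacing: float = 1.0) -> PolyLattice:
    """Square lattice with Moore (8-site) adjacency and uniform weights.

    Diagonal contacts share only a corner; they are kept in the adjacency with
    ``l_ij = 0`` so the neighbor-pick rule sees all 8 sites, but they carry no
    edge length.  In ``uniform`` mode (the default and the classic CPM
    convention) every one of the 8 contacts has weight 1.
    """
    if n_cols < 3 or n_rows < 3:
        raise ValueError("need n_cols, n_rows >= 3 for unambiguous periodic adjacency")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    a = float(spacing)
    box = PeriodicBox(n_cols * a, n_rows * a)
    sites = []
    unit = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]) * a
    for r in range(n_rows):
        for c in range(n_cols):
            sid = r * n_cols + c
            verts = unit + np.array([c * a, r * a])
            nbr, lens = [], []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    j = ((r + dr) % n_rows) * n_cols + (c + dc) % n_cols
                    nbr.append(j)
                    lens.append(a if abs(dr) + abs(dc) == 1 else 0.0)
            area, cen = _polygon_area_centroid(verts)
            sites.append(LatticeSite(sid, verts, cen, area,
                                     np.array(nbr, dtype=np.int64),
                                     np.array(lens)))
    return PolyLattice(box, sites, weight_mode="uniform")


def build_hexagonal(n_cols: int, n_rows: int, cell_area: float) -> PolyLattice:
    """Regular hexagonal lattice (pointy-top, offset rows), 6 neighbors per site.

    All edges share the same length, so uniform and edge-weighted modes
    coincide (every ``w_ij = 1``).  ``n_rows`` must be even for the offset
    tiling to close periodically.
    """
    if n_rows % 2 != 0:
        raise ValueError("n_rows must be even for a periodic hexagonal tiling")
    if n_cols < 3 or n_rows < 4:
        raise ValueError("need n_cols >= 3 and n_rows >= 4")
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    R = math.sqrt(cell_area / (1.5 * math.sqrt(3.0)))  # circumradius = side
    w = math.sqrt(3.0) * R
    pitch = 1.5 * R
    box = PeriodicBox(n_cols * w, n_rows * pitch)
    ang = np.deg2rad(90 + 60 * np.arange(6))
    hexverts = R * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    sites = []
    for r in range(n_rows):
        for c in range(n_cols):
            sid = r * n_cols + c
            cx = (c + 0.5 * (r % 2)) * w
            cy = r * pitch + R  # shift so row 0 sits inside the box
            verts = hexverts + np.array([cx, cy])
            off = 0 if r % 2 == 0 else 1  # col offset of upper/lower neighbors
            nbr = [
                r * n_cols + (c - 1) % n_cols,
                r * n_cols + (c + 1) % n_cols,
                ((r + 1) % n_rows) * n_cols + (c - 1 + off) % n_cols,
                ((r + 1) % n_rows) * n_cols + (c + off) % n_cols,
                ((r - 1) % n_rows) * n_cols + (c - 1 + off) % n_cols,
                ((r - 1) % n_rows) * n_cols + (c + off) % n_cols,
            ]
            area, cen = _polygon_area_centroid(verts)
            sites.append(LatticeSite(sid, verts, cen, area,
                                     np.array(nbr, dtype=np.int64),
                                     np.full(6, R)))
    return PolyLattice(box, sites, weight_mode="uniform")


# ---------------------------------------------------------------------------
# periodic Voronoi builder
# ---------------------------------------------------------------------------

def build_voronoi(points: np.ndarray, box: PeriodicBox, *,
                  merge_tol: float = 1e-9,
                  self_contact: str = "raise") -> PolyLattice:
    """Periodic Voronoi tessellation of a point set.

    The generators are replicated into the 8 surrounding periodic images, the
    3x3 supercell is tessellated, central-copy cells are kept, and image
    adjacencies are folded back onto the original ids.  Two sites are adjacent
    iff their polygons share at least one (merged) Voronoi vertex; vertex-only
    contacts get ``l_ij = 0``.  If a pair touches across several periodic
    images their contact lengths are summed into one adjacency entry.

    Parameters
    ----------
    points : (n, 2) array of generators (wrapped into ``box``).
    box : PeriodicBox
    merge_tol : float
        Voronoi vertices closer than this are identified before adjacency
        extraction (floating-point tessellations emit near-duplicate vertices
        at degenerate, co-circular configurations).
    self_contact : {"raise", "ignore"}
        What to do when a generator's cell touches its own periodic image
        (box too small relative to the point sparsity).  ``ignore`` drops the
        self-contacts from the adjacency and keeps the lattice.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 generators")
    if self_contact not in ("raise", "ignore"):
        raise ValueError("self_contact must be 'raise' or 'ignore'")
    pts = box.wrap(pts)

    # duplicate generators under the minimum image
    tree = cKDTree(pts, boxsize=[box.Lx, box.Ly])
    if tree.query_pairs(1e-9):
        raise ValueError("duplicate generators (coincident within 1e-9)")

    offsets = [(0, 0)] + [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
                          if (dx, dy) != (0, 0)]
    shift = np.array([[dx * box.Lx, dy * box.Ly] for dx, dy in offsets])
    pts9 = np.concatenate([pts + s for s in shift])
    vor = Voronoi(pts9)

    # merge near-duplicate Voronoi vertices -> canonical label per vertex id
    label = np.arange(len(vor.vertices))
    vtree = cKDTree(vor.vertices)
    for a, b in vtree.query_pairs(merge_tol):
        ra, rb = label[a], label[b]
        if ra != rb:
            label[label == max(ra, rb)] = min(ra, rb)

    # vertex label -> incident generator indices (over the whole supercell)
    incident: dict[int, set[int]] = {}
    for p_idx, reg_idx in enumerate(vor.point_region):
        region = vor.regions[reg_idx]
        if -1 in region:
            continue  # unbounded copies on the supercell rim
        for v in region:
            incident.setdefault(label[v], set()).add(p_idx)

    # contact lengths from ridges touching a central cell
    lengths: dict[tuple[int, int], float] = {}
    for (a, b), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 < 0 or v2 < 0:
            continue
        la, lb = label[v1], label[v2]
        if la == lb:
            continue  # degenerate zero-length ridge
        length = float(np.linalg.norm(vor.vertices[v1] - vor.vertices[v2]))
        for i, other in ((a, b), (b, a)):
            if i < n:
                lengths[(i, other)] = lengths.get((i, other), 0.0) + length

    # adjacency by shared vertex, folded back onto original ids
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    self_touch = set()
    for cells in incident.values():
        central = [c for c in cells if c < n]
        for i in central:
            for m in cells:
                j = m % n
                if m == i:
                    continue
                if j == i:
                    self_touch.add(i)
                    continue
                adj[i].setdefault(j, 0.0)
    for (i, m), length in lengths.items():
        j = m % n
        if i >= n:
            continue
        if j == i:
            self_touch.add(i)
            continue
        adj[i][j] = adj[i].get(j, 0.0) + length
    if self_touch and self_contact == "raise":
        raise ValueError(
            f"generator(s) {sorted(self_touch)} touch their own periodic image; "
            "box too small relative to point sparsity")

    # symmetrize contact lengths (each direction accumulated independently;
    # average washes out last-digit float noise)
    for i in range(n):
        for j in list(adj[i]):
            lij = 0.5 * (adj[i][j] + adj[j].get(i, adj[i][j]))
            adj[i][j] = lij
            adj[j][i] = lij

    sites = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise ValueError(f"unbounded or degenerate cell for generator {i}")
        # deduplicate merged vertices, keep one coordinate per label
        seen, verts = set(), []
        for v in region:
            if label[v] not in seen:
                seen.add(label[v])
                verts.append(vor.vertices[v])
        verts = np.array(verts)
        cen0 = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - cen0[1], verts[:, 0] - cen0[0]))
        verts = _ccw(verts[order])
        area, cen = _polygon_area_centroid(verts)
        nbr = np.array(sorted(adj[i]), dtype=np.int64)
        lens = np.array([adj[i][j] for j in nbr])
        sites.append(LatticeSite(i, verts, cen, area, nbr, lens))
    return PolyLattice(box, sites, weight_mode="edge-weighted")


# ---------------------------------------------------------------------------
# serialization (JSON lattice dialect)
# ---------------------------------------------------------------------------

def save_lattice(lattice: PolyLattice, path) -> None:
    """Write the lattice to the JSON dialect (full float precision)."""
    doc = {
        "box": {"Lx": lattice.box.Lx, "Ly": lattice.box.Ly},
        "weight_mode": lattice.weight_mode,
        "sites": [
            {
                "id": s.id,
                "vertices": s.vertices.tolist(),
                "neighbors": s.neighbor_ids.tolist(),
                "edge_lengths": s.edge_lengths.tolist(),
            }
            for s in lattice.sites
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_lattice(path) -> PolyLattice:
    """Read a lattice written by :func:`save_lattice`; validates all invariants."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise LatticeFormatError(f"not valid JSON: {exc}") from exc
    for key in ("box", "weight_mode", "sites"):
        if key not in doc:
            raise LatticeFormatError(f"missing top-level field {key!r}")
    try:
        box = PeriodicBox(float(doc["box"]["Lx"]), float(doc["box"]["Ly"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise LatticeFormatError(f"bad 'box' field: {exc}") from exc
    sites = []
    for rec in doc["sites"]:
        try:
            verts = np.asarray(rec["vertices"], dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 3:
                raise ValueError("vertices must be an (m>=3, 2) ring")
            area, cen = _polygon_area_centroid(_ccw(verts))
            sites.append(LatticeSite(
                int(rec["id"]), _ccw(verts), cen, area,
                np.asarray(rec["neighbors"], dtype=np.int64),
                np.asarray(rec["edge_lengths"], dtype=float)))
        except (KeyError, TypeError, ValueError) as exc:
            raise LatticeFormatError(
                f"bad site record {rec.get('id', '?')}: {exc}") from exc
    ids = sorted(s.id for s in sites)
    if ids != list(range(len(sites))):
        raise LatticeFormatError("site ids must be a dense 0..N-1 range")
    sites.sort(key=lambda s: s.id)
    try:
        return PolyLattice(box, sites, weight_mode=doc["weight_mode"])
    except ValueError as exc:
        raise LatticeFormatError(str(exc)) from exc
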