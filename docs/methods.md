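# Methods

## Model

The cellular Potts model (CPM, also Glazier–Graner–Hogeweg model) describes
a confluent tissue as a map σ from lattice sites to cell indices: cell c
occupies the set of sites with σ(i) = c, and every site belongs to exactly
one cell.  On an arbitrary periodic polygonal lattice the Hamiltonian is

    H = α Σ_{⟨i,j⟩} w_ij [σ(i) ≠ σ(j)]  +  λ Σ_c (a_c − A0)²

where the first sum runs over distinct adjacent site pairs, each counted
once.  α is the surface tension between unlike cells, λ the area-spring
strength penalizing departures of the instantaneous cell area a_c from the
target A0 (a 2D proxy for volume conservation).  The weight

    w_ij = l_ij / l̄

is the shared-boundary length of sites i and j divided by the mean edge
length of the lattice, so the surface energy is proportional to physical
contact length on irregular lattices; on regular lattices all w_ij = 1 and
the classical CPM Hamiltonian is recovered.  Counting each unordered pair
once fixes the scale of α; a double-counting convention would merely
rescale α by 2.

Two sites are adjacent iff their polygons share at least one vertex.  On
the square lattice this is the 8-site Moore neighborhood; the four diagonal
contacts share only a corner and carry l_ij = 0.  In uniform-weight mode
(the regular-lattice default) they still carry weight 1; in edge-weighted
mode they would carry weight 0 — a documented deviation from the classic
Moore CPM, which is why regular builders default to uniform weights.
Vertex-only contacts remain in the neighbor list for move proposals but
contribute no surface energy in edge-weighted mode.  l̄ averages each
distinct positive-length edge once; zero-length contacts are not edges.

## Dynamics

Metropolis Monte-Carlo: an attempt picks a candidate site i uniformly among
all N_s sites and an invading site j uniformly from i's full neighbor list
(an optional `neighbor_pick="length_weighted"` switch samples j with
probability ∝ l_ij instead; the uniform rule is the default and all results
here use it).  If σ(i) = σ(j) the attempt is a no-op but still advances the
clock; otherwise σ(i) → σ(j) is accepted with probability
min(1, exp(−ΔE/k_BT)).  One sweep (MCS) is N_s attempts; k_BT = 1
throughout, so temperature only sets the membrane-fluctuation rate.  ΔE is
computed locally from the candidate's adjacency row and the two affected
cell areas, and is contract-tested against the full Hamiltonian difference
to 1e−10.

No connectivity constraint is imposed (none is needed at the surface
tensions studied); `fragmentation_report` passively counts the connected
components of each cell under positive-length adjacency as a run-health
check.

All randomness of a run comes from one explicit xorshift128+ stream seeded
via splitmix64, consumed in fixed order (site pick, neighbor pick,
acceptance draw), making every run bit-reproducible from its seed.  The
hot loop is JIT-compiled (numba) over flat CSR adjacency arrays
(~40 M attempts/s on one core for ~10³-site lattices).  Incremental cell
areas are refreshed from scratch at every sample to shed float drift; the
refreshed values are identical to the incremental ones to ~1e−12.

Initial conditions: a 5 × 8 rectangular tiling of the box (the fluid-side
standard), or a hexagonal tiling of cells of area A0 assigned by nearest
tiling center (the crystalline start used for the solid branch; it replaces
an equilibrated near-transition snapshot, which only changes the required
equilibration time).  Cell evaporation (zero area) aborts a strict run.

## Irregular lattices

Uniform-random Voronoi generators produce strongly polydisperse cells, so
the disordered lattice is generated from a *fluid* configuration instead: a
square-lattice CPM run at α = 0.8 (λ = k_BT = 1, A0 = 40) starting from the
5 × 8 rectangle tiling; after equilibration the periodic-aware cell centers
of mass are rescaled onto a target box exactly tileable by hexagons of area
A0 (so crystalline initial conditions fit), and periodically
Voronoi-tessellated.  The tessellation replicates the generators into the
8 surrounding images, tessellates the 3 × 3 supercell with scipy/Qhull,
keeps the central cells and folds image adjacencies back onto original ids,
summing contact lengths when a pair touches across several images.
Voronoi vertices closer than 1e−9 are merged to heal floating-point
duplicates at degenerate (co-circular) configurations.  A generator whose
cell touches its own periodic image signals a box too small relative to the
point sparsity and is rejected by default.

Structural isotropy is verified spectrally rather than by visual FFT
inspection: the centers are rasterized to a 512² binary image, and the
anisotropy score is the coefficient of variation of the 2D power spectrum
across 36 angular bins restricted to the first structure-factor ring
(|k| ∈ [0.7, 1.3] × 2π/u, with u = √(box area / N) the mean cell spacing).
Six-fold Bragg peaks of a triangular lattice score ≳ 10× the uniform-random
baseline; the fluid-derived lattices score within 2× of it.  Lattice QA
thresholds: site-area CV < 0.25, site degree within 4..10.

## Characterization

**MSD, β, D_eff.**  Cell centers of mass are tracked unwrapped (minimum-
image displacements relative to the previous sample).  The MSD uses a
single time origin at the end of equilibration,
⟨r²(t)⟩ = ⟨(r(t + t_w) − r(t_w))²⟩, averaged over cells and — crucially at
reduced size — over independent runs pooled into one ensemble: collective
fluctuations correlate all cells of one run, so a single ~100-cell run
yields an unusably noisy exponent.  β is the least-squares slope of
log ⟨r²⟩ vs log t over the last decade of lag times (window configurable),
and D_eff = mean(⟨r²⟩/4t) over the window, reported only when
|β − 1| ≤ max(0.05, SE(β)) — the diffusive gate.  In α-scan aggregation the
gate is applied at the ensemble level (mean per-run β against its SEM
across independent runs), since the per-run ordinary-least-squares error
wildly understates the true run-to-run spread.  A caging transient precedes
the diffusive regime (⟨r²⟩ of order the cell area, i.e. lags ≲ A0/4D_eff),
so sampling windows are lengthened as α approaches the transition.

**Hexatic order.**  ψ6(k) = (1/6) Σ_{j∈N(k)} exp(6iθ(j,k)) over the six
nearest cell centers under the minimum image, with θ the counterclockwise
angle from the x-axis; distance ties are broken by (distance, id) so
symmetric center arrangements give deterministic output.  ⟨|ψ6|⟩ averages
over cells and samples.

**Voronoi shape metrics.**  Lattice cell borders are jagged (the lattice
metric inflates perimeters), so shapes are measured on the periodic Voronoi
tessellation of the cell centers, as vertex/Voronoi models define cells.
The isoperimetric quotient is q = √(4πA)/P (1 for a disk; the classical
4πA/P² equals q² and is exposed separately).  For a regular n-gon with
circumradius r, A = (n/2)r² sin(2π/n) and P = 2nr sin(π/n) give the
closed form q_reg(n), valid for real n ≥ 3, strictly increasing, → 1 as
n → ∞.  Inverting it (Brent bracketing, |Δq| < 1e−12) defines the
generalized edge number n*(q); pseudo-n-gons are cells with
n − ½ < n* ≤ n + ½ and f_n their fractions.  The circularity
C = A²/(2π tr Ī) uses the centroidal second-moment-of-area tensor from
closed-form shoelace moments (C = 1 for a disk; C(4) = 3/π); the analogous
C_reg(n) = 3n sin(2π/n)/(2π(2 + cos(2π/n))) is inverted the same way to
define n°, and C(5) — the regular-pentagon circularity — is the
transition-indicator reference.  Although inverting C is numerically
harsher than inverting q (C is much flatter in n near 6), the inversion is
provided and round-trips to 1e−9.

**Distribution extrema.**  Histograms use 60 bins by default; peak and
interior-minimum positions are refined by local quadratic fits over ±3 bins.
Bimodality requires a second local maximum of at least 5% of the main
peak's height whose persistence above the interior valley exceeds twice the
combined bin SEM — this rejects Poisson bumps in thin tails.

## Transition localization

Three indicators, all operating on the per-α scan table:

1. **Diffusion.**  A least-squares polynomial (default degree 4, degrees
   3–6 accepted) is fitted to log₁₀ D_eff vs α over the gate-passing
   points.  The *inflection* of the fit (curvature sign-change root nearest
   the steepest descent) marks mid-coexistence and overestimates the
   transition; the *drop-off* (most negative curvature inside a 10%
   margin-trimmed grid) marks the end of the purely disordered branch and
   always precedes the inflection.  A global polynomial localizes the
   inflection of a sigmoidal drop essentially exactly, but biases the
   curvature minimum well below the midpoint — a known limitation of this
   estimator class, which is why the drop-off is reported as a lower
   bracket rather than a point estimate of the transition.  Strictly linear
   data raise "no transition in range".
2. **Pseudo-polygon crossover.**  α at f6/f5 = 1, by linear interpolation
   of log(f6/f5) between the bracketing grid points (to order, the system
   crystallizes when pseudo-hexagons outnumber pseudo-pentagons).
3. **Circularity mode.**  α at mode(C_V) = C(5), by linear interpolation of
   mode(C_V) − C(5).

## Synthetic data

The synthetic generators used in validation emulate: 2D Gaussian random
walks (known D = s²/2) and ballistic tracks (β = 2) for the MSD chain; and
a sigmoidal α scan (logistic drop of log₁₀ D_eff of width 0.1 centered on
α₀, complementary logistic f5/f6 crossing at α₀, mode(C_V) crossing C(5) at
α₀) for the transition estimators.  They deliberately do not emulate the
correlated, non-Gaussian fluctuations of interacting tissues, so passing
these recoveries validates the estimator arithmetic, not the physics; the
physics checks are the reduced-size simulations below.

## Reduced study conditions

The reference study conditions are λ = 1, A0 = 40, k_BT = 1, ~10³ cells on
~4 × 10⁴-site lattices, α ∈ [1, 4], with 2 × 10⁵–8 × 10⁶-sweep protocols
and 20–50 independent runs per α.  This package's shipped tests and the
acceptance script keep all intensive parameters and the per-cell resolution
(~40 sites per cell) identical but reduce the cell number to ~120 (4800
lattice sites) and the ensemble to 2–3 runs, with 10⁴–10⁵-sweep windows.
Choices and measured consequences:

* ~120 cells is the smallest size found to preserve the fluid phase at
  α = 1.8 (bimodal n* distribution with interior minimum at n* ≈ 4.9, ψ6
  ≈ 0.63); at ~70 cells the system orders prematurely.
* The solid state at α = 2.6 reproduces the shared n* peak at ≈ 5.74 and
  intact (unfragmented) cells.  Its equilibrium hexatic order at this size
  is ⟨|ψ6|⟩ ≈ 0.83 (0.86 on the regular hexagonal lattice), saturating
  near 0.85 by α = 4: a T = 0 quench of the thermal state retains
  ψ6 ≈ 0.84 while a pristine crystal relaxed at T = 0 reaches 0.97, i.e.
  the depression is equilibrium structural disorder at k_BT = 1, not
  statistics.
* The reduced α scan brackets the order–disorder transition at α ≈ 2.1
  (hexatic rise through ≈ 0.76, f6/f5 crossover, mode(C_V) = C(5)
  crossing), consistent with a first-order fluid→hexagonal-solid scenario;
  finite-size shifts of order ±0.1 in α are expected.

## Known limitations

* The drop-off (curvature-minimum) estimator inherits the global-polynomial
  bias described above; treat it as the lower edge of the transition
  window.
* Single-run MSD exponents at ≲10² cells are dominated by collective
  fluctuations; always pool independent runs.
* Voronoi-smoothed shapes differ from the raw lattice cell shapes by
  construction; all q_V, n*, C_V statements refer to the Voronoi polygons.
* No free-energy or finite-size-scaling analysis is attempted; the
  estimators report indicators, not a classification of the transition
  order.
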