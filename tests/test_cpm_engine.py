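"""Potts engine: energies, Metropolis rule, initializers, run protocol."""

import numpy as np
import pytest

from polypotts import observables
from polypotts.cpm_engine import (CpmRng, SimParams, SpinField, attempt,
                                  cell_cms, delta_energy, fragmentation_report,
                                  init_hexagonal_cells, init_rectangles, run,
                                  run_sweeps, sweep, total_energy,
                                  _metropolis)
from polypotts.polylattice import PolyLattice, build_hexagonal, build_square


def two_column_field(lat):
    """4x4 square lattice split into two 2-column cells."""
    spin = np.array([1 if (i % 4) < 2 else 2 for i in range(16)])
    return SpinField(spin, 2, lat)


class TestTotalEnergy:
    def test_single_cell_at_target(self):
        lat = build_square(4, 4, 1.0)
        f = SpinField(np.ones(16, dtype=int), 1, lat)
        e = total_energy(lat, f, SimParams(alpha=1.0, lam=1.0, A0=16.0))
        assert e.total == 0.0

    def test_area_penalty_only(self):
        lat = build_square(4, 4, 1.0)
        f = SpinField(np.ones(16, dtype=int), 1, lat)
        e = total_energy(lat, f, SimParams(alpha=1.0, lam=1.0, A0=12.0))
        assert e.surface == 0.0
        assert e.area == pytest.approx(16.0)

    def test_two_column_interface_by_enumeration(self):
        # independent count of unlike-spin Moore pairs on the 4x4 torus
        lat = build_square(4, 4, 1.0)
        f = two_column_field(lat)
        count = 0
        for r in range(4):
            for c in range(4):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if (dr, dc) == (0, 0):
                            continue
                        c2 = (c + dc) % 4
                        if (c < 2) != (c2 < 2):
                            count += 1
        count //= 2  # each unordered pair seen twice
        assert count == 24
        e = total_energy(lat, f, SimParams(alpha=1.0, lam=1e-300, A0=8.0))
        assert e.surface == pytest.approx(24.0)


class TestDeltaEnergy:
    @pytest.mark.parametrize("builder,args", [
        (build_square, (6, 6, 1.0)),
        (build_hexagonal, (6, 6, 2.0)),
    ])
    def test_matches_total_energy_difference(self, builder, args):
        lat = builder(*args)
        rng = np.random.default_rng(0)
        spin = rng.integers(1, 5, size=lat.n_sites)
        f = SpinField(spin, 4, lat)
        p = SimParams(alpha=1.3, lam=0.7, A0=9.0)
        for _ in range(300):
            i = rng.integers(lat.n_sites)
            s = rng.integers(1, 5)
            if s == f.spin[i]:
                continue
            dE = delta_energy(lat, f, p, int(i), int(s))
            g = f.copy()
            g.spin[i] = s
            g.refresh_areas(lat)
            brute = total_energy(lat, g, p).total - total_energy(lat, f, p).total
            assert dE == pytest.approx(brute, abs=1e-10)

    def test_same_spin_rejected(self):
        lat = build_square(4, 4, 1.0)
        f = two_column_field(lat)
        with pytest.raises(ValueError, match="same-spin"):
            delta_energy(lat, f, SimParams(alpha=1.0), 0, int(f.spin[0]))

    def test_interface_flip_local_enumeration(self):
        # flipping an interface site changes the surface term by the change
        # in unlike-pair count over its 8 Moore contacts
        lat = build_square(4, 4, 1.0)
        f = two_column_field(lat)
        p = SimParams(alpha=1.0, lam=1e-300, A0=8.0)
        site = 1  # column 1, adjacent to the interface
        before = sum(1 for j in lat.sites[site].neighbor_ids
                     if f.spin[j] != f.spin[site])
        after = sum(1 for j in lat.sites[site].neighbor_ids
                    if f.spin[j] != 2)
        dE = delta_energy(lat, f, p, site, 2)
        assert dE == pytest.approx(after - before, abs=1e-12)


class TestMetropolis:
    def test_half_acceptance_at_kT_ln2(self):
        state = CpmRng(123).state
        dE = np.log(2.0)
        n = 100_000
        acc = sum(_metropolis(dE, 1.0, state) for _ in range(n))
        sigma = np.sqrt(n * 0.5 * 0.5)
        assert abs(acc - n / 2) < 3 * sigma

    def test_downhill_always_accepted(self):
        state = CpmRng(1).state
        assert all(_metropolis(-x, 1.0, state) for x in (0.0, 0.1, 5.0))

    def test_zero_temperature_limit(self):
        state = CpmRng(7).state
        assert not any(_metropolis(1e-6, 1e-12, state) for _ in range(10_000))


class TestSweep:
    def test_frozen_single_cell_state(self):
        lat = build_square(4, 4, 1.0)
        f = SpinField(np.ones(16, dtype=int), 1, lat)
        p = SimParams(alpha=1.0, lam=1.0, A0=16.0)
        assert sweep(lat, f, p, CpmRng(0)) == 0

    def test_deterministic_given_seed(self):
        lat = build_square(8, 8, 1.0)
        p = SimParams(alpha=1.0, lam=1.0, A0=8.0)
        outs = []
        for _ in range(2):
            f = init_rectangles(lat, 4.0, 2.0)
            acc = sum(sweep(lat, f, p, CpmRng(99)) for _ in range(5))
            outs.append((acc, f.spin.copy()))
        assert outs[0][0] == outs[1][0]
        assert np.array_equal(outs[0][1], outs[1][1])

    def test_vanishing_couplings_accept_everything_unlike(self):
        # with alpha, lam -> 0 every unlike-spin proposal has dE -> 0
        lat = build_square(8, 8, 1.0)
        f = init_rectangles(lat, 4.0, 4.0)
        p = SimParams(alpha=1e-300, lam=1e-300, A0=16.0)
        acc = sum(sweep(lat, f, p, CpmRng(3)) for _ in range(20))
        assert acc > 0.2 * 20 * lat.n_sites  # most picks are unlike near mixing

    def test_incremental_bookkeeping_matches_recomputation(self):
        lat = build_square(20, 20, 1.0)
        f = init_rectangles(lat, 5.0, 8.0)
        p = SimParams(alpha=1.2, lam=1.0, A0=40.0, kT=1.0)
        rng = CpmRng(5)
        run_sweeps(lat, f, p, rng, 50)  # 20k attempts
        assert np.abs(f.cell_area - f.recomputed_areas(lat)).max() < 1e-8
        e_inc = total_energy(lat, f, p)
        f.refresh_areas(lat)
        assert total_energy(lat, f, p).total == pytest.approx(e_inc.total,
                                                              abs=1e-8)

    def test_zero_temperature_quench_decreases_energy(self):
        lat = build_square(20, 20, 1.0)
        f = init_rectangles(lat, 5.0, 8.0)
        p = SimParams(alpha=3.0, lam=1.0, A0=40.0, kT=1e-12)
        rng = CpmRng(8)
        energies = [total_energy(lat, f, p).total]
        for _ in range(10):
            sweep(lat, f, p, rng)
            energies.append(total_energy(lat, f, p).total)
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-9)


class TestWeightModes:
    def test_uniform_and_edge_weighted_agree_on_hexagonal(self):
        lat_u = build_hexagonal(6, 6, 4.0)
        lat_w = PolyLattice(lat_u.box, lat_u.sites, weight_mode="edge-weighted")
        rng = np.random.default_rng(4)
        spin = rng.integers(1, 4, size=lat_u.n_sites)
        p = SimParams(alpha=1.7, lam=0.5, A0=12.0)
        f = SpinField(spin, 3, lat_u)
        for _ in range(100):
            i = int(rng.integers(lat_u.n_sites))
            s = int(rng.integers(1, 4))
            if s == f.spin[i]:
                continue
            d1 = delta_energy(lat_u, f, p, i, s)
            d2 = delta_energy(lat_w, f, p, i, s)
            assert d1 == pytest.approx(d2, abs=1e-12)


class TestInitializers:
    def test_rectangles_counts_and_confluency(self):
        lat = build_square(40, 40, 1.0)
        f = init_rectangles(lat, 5.0, 8.0)
        assert f.n_cells == 8 * 5
        assert np.allclose(f.cell_area[1:], 40.0)
        assert f.cell_area[1:].sum() == pytest.approx(lat.box.area)

    def test_two_equal_rectangles(self):
        lat = build_square(10, 8, 1.0)
        f = init_rectangles(lat, 5.0, 8.0)
        assert f.n_cells == 2
        assert np.allclose(f.cell_area[1:], 40.0)

    def test_hexagonal_cells_order_and_confluency(self, hex_lattice):
        f = init_hexagonal_cells(hex_lattice, 40.0)
        assert f.cell_area[1:].sum() == pytest.approx(hex_lattice.box.area)
        centers = cell_cms(hex_lattice, f)
        h = observables.psi6(centers, hex_lattice.box)
        assert h.mean_abs >= 0.99
        # honeycomb of cells: each cell has 6 neighbor cells
        frag = fragmentation_report(hex_lattice, f)
        assert set(frag.values()) == {1}

    def test_untileable_box_suggests_dimensions(self):
        lat = build_square(10, 10, 1.0)
        with pytest.raises(ValueError, match="nearest tileable"):
            init_hexagonal_cells(lat, 40.0)


class TestCellCms:
    def test_minimum_image_straddling_cell(self):
        lat = build_square(8, 8, 1.0)
        # cell 1 occupies columns 0 and 7 -> CMS on the seam, not mid-box
        col = np.arange(64) % 8
        spin = np.where((col == 0) | (col == 7), 1, 2)
        f = SpinField(spin, 2, lat)
        cms = cell_cms(lat, f)
        x = cms[0, 0] % 8.0
        assert min(x, 8.0 - x) < 0.51

    def test_translation_equivariance(self):
        import dataclasses

        from polypotts.polylattice import PolyLattice
        lat = build_square(8, 8, 1.0)
        f = init_rectangles(lat, 4.0, 4.0)
        a = cell_cms(lat, f)
        delta = np.array([0.6, -1.3])
        moved = PolyLattice(lat.box, [
            dataclasses.replace(s, vertices=s.vertices + delta,
                                centroid=s.centroid + delta)
            for s in lat.sites], weight_mode=lat.weight_mode)
        b = cell_cms(moved, f, prev_positions=a + delta)
        assert np.allclose(b, a + delta, atol=1e-9)

    def test_single_site_cell_is_its_centroid(self):
        lat = build_square(4, 4, 1.0)
        spin = np.full(16, 2)
        spin[5] = 1
        f = SpinField(spin, 2, lat)
        cms = cell_cms(lat, f)
        assert np.allclose(cms[0], lat.sites[5].centroid)


class TestRunProtocol:
    def test_zero_length_run_single_sample(self):
        lat = build_square(8, 8, 1.0)
        f = init_rectangles(lat, 4.0, 4.0)
        traj = run(lat, f, SimParams(alpha=1.0, A0=16.0, t_w=0, t_s=0))
        assert traj.n_samples == 1
        assert traj.times[0] == 0

    def test_bit_identical_trajectories(self):
        lat = build_square(16, 16, 1.0)
        p = SimParams(alpha=1.5, A0=16.0, seed=21, t_w=20, t_s=100,
                      sample_every=20)
        t1 = run(lat, init_rectangles(lat, 4.0, 4.0), p)
        t2 = run(lat, init_rectangles(lat, 4.0, 4.0), p)
        assert np.array_equal(t1.positions, t2.positions)
        assert t1.acceptance_rate == t2.acceptance_rate

    def test_confluency_at_every_sample(self):
        lat = build_square(16, 16, 1.0)
        seen = []

        def watch(t, lattice, field, positions):
            seen.append(field.cell_area[1:].sum())

        p = SimParams(alpha=1.5, A0=16.0, seed=2, t_w=50, t_s=200,
                      sample_every=50)
        run(lat, init_rectangles(lat, 4.0, 4.0), p, observers=[watch])
        assert np.allclose(seen, lat.box.area, rtol=1e-8)


class TestFragmentation:
    def test_intact_rectangles(self):
        lat = build_square(16, 16, 1.0)
        f = init_rectangles(lat, 4.0, 4.0)
        assert set(fragmentation_report(lat, f).values()) == {1}

    def test_split_cell_detected(self):
        lat = build_square(8, 8, 1.0)
        spin = np.full(64, 2)
        spin[0] = 1          # two sites of cell 1 in opposite corners,
        spin[8 * 4 + 4] = 1  # not adjacent -> two components
        f = SpinField(spin, 2, lat)
        assert fragmentation_report(lat, f)[1] == 2
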