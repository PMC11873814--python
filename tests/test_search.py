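"""The grid search: layering, frames, candidate construction, recovery."""

import numpy as np
import pytest

from zonecell.datasets import cupc_patterns, lysozyme_patterns
from zonecell.lattice import UnitCell, cells_equivalent, reciprocal_of, direct_of
from zonecell.patterns import ZonePattern
from zonecell.search import (
    ScanConfig,
    ScanFrame,
    build_candidate_cell,
    candidate_grid,
    fom_surface,
    search,
    select_initial_zone,
    vmin_default,
    volume_layers,
)
from zonecell.synthetic import SimulationSpec, simulate_dataset, simulate_zone_pattern
from zonecell.zones import zone_net

from conftest import make_random_cell


class TestVolumeLayers:
    def test_published_ladder(self):
        layers = volume_layers(763.0, 1000.0, 0.025)
        assert len(layers) == 12
        expect = [763.0, 782.1, 801.6, 821.7, 842.2, 863.3, 884.8,
                  907.0, 929.6, 952.9, 976.7, 1001.1]
        assert layers == pytest.approx(expect, abs=0.05)

    def test_single_layer(self):
        assert volume_layers(100.0, 100.0, 0.3) == [100.0]

    def test_iteration_oracle(self):
        layers = volume_layers(500.0, 600.0, 0.05)
        assert layers == pytest.approx([500, 525, 551.25, 578.8125, 607.753125])


class TestFrame:
    def test_vmin_from_base_area(self):
        frame = ScanFrame.from_pattern(ZonePattern("7", 14.15, 14.45, 68.0))
        assert frame.area == pytest.approx(220.5, abs=0.1)
        assert vmin_default(frame, h_min=3.46) == pytest.approx(763.0, abs=1.0)

    def test_square_net(self):
        frame = ScanFrame.from_pattern(ZonePattern("s", 10.0, 10.0, 90.0))
        assert vmin_default(frame, h_min=3.4) == pytest.approx(340.0)

    def test_p4_regularizes_lengths_and_angle(self):
        frame = ScanFrame.from_pattern(ZonePattern("1", 79.0, 79.12, 89.8, symmetry="p4"))
        assert frame.a_star == frame.b_star
        assert frame.gamma_star == 90.0

    def test_cmm_centred_rectangular_goes_diagonal(self):
        # the centred-rectangular descriptor re-expresses on equal-length diagonals
        frame = ScanFrame.from_pattern(ZonePattern("1", 13.82, 4.39, 80.9, symmetry="cmm"))
        assert frame.a_star == frame.b_star
        assert frame.a_star == pytest.approx(1 / 4.39, rel=0.01)
        assert frame.gamma_star == pytest.approx(18.3, abs=0.2)


class TestCandidateGrid:
    def test_p4_two_points_per_layer(self):
        layers = volume_layers(763.0, 1000.0, 0.025)
        grid = candidate_grid("p4", layers, 1 / 12)
        assert len(grid) == 24
        assert {(xi, eta) for xi, eta, _ in grid} == {(0.0, 0.0), (0.5, 0.5)}

    def test_p6_points(self):
        grid = candidate_grid("p6", [100.0], 1 / 12)
        assert {(xi, eta) for xi, eta, _ in grid} == {(0.0, 0.0), (1 / 3, 1 / 3)}

    def test_p1_counting_oracle(self):
        step = 1 / 8
        grid = candidate_grid("p1", [100.0], step)
        xs = np.arange(-0.5, 0.5 - 1e-9, step)
        es = np.arange(0.0, 0.5 + 1e-9, step)
        assert len(grid) == len(xs) * len(es)

    def test_pmm_four_lines(self):
        grid = candidate_grid("pmm", [100.0], 1 / 8)
        tags = {(xi, eta) for xi, eta, _ in grid}
        assert (0.0, 0.25) in tags and (0.5, 0.25) in tags
        assert (0.25, 0.0) in tags and (0.25, 0.5) in tags

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            candidate_grid("p3", [100.0], 1 / 8)


class TestBuildCandidateCell:
    def test_perpendicular_c_star_at_origin(self):
        frame = ScanFrame.from_pattern(ZonePattern("x", 10.0, 12.0, 80.0))
        rcell = build_candidate_cell(frame, 0.0, 0.0, 900.0)
        assert rcell.alpha_star == pytest.approx(90.0)
        assert rcell.beta_star == pytest.approx(90.0)

    def test_interlayer_spacing(self):
        # base area 220.5 Å² and V = 842 Å³ give the known 3.82 Å short axis
        frame = ScanFrame.from_pattern(ZonePattern("7", 14.15, 14.45, 68.0))
        rcell = build_candidate_cell(frame, 0.0, 0.0, 842.0)
        assert 1.0 / rcell.c_star == pytest.approx(3.819, abs=0.005)

    def test_direct_volume_matches_exactly(self, rng):
        frame = ScanFrame.from_pattern(ZonePattern("x", 8.0, 11.0, 75.0))
        for _ in range(20):
            xi, eta = rng.uniform(-0.5, 0.5, 2)
            volume = rng.uniform(200, 2000)
            rcell = build_candidate_cell(frame, xi, eta, volume)
            assert direct_of(rcell).volume == pytest.approx(volume, rel=1e-9)

    def test_round_trip_rebuilds_known_cell(self, rng):
        """The (ξ, η, V) of the true c* reconstructs the generating cell."""
        cell = make_random_cell(rng)
        net = zone_net(cell, (0, 0, 1))
        pattern = simulate_zone_pattern(cell, (0, 0, 1))
        frame = ScanFrame.from_pattern(pattern)
        # true c* expressed in the frame (from the reciprocal basis geometry)
        from zonecell.lattice import basis_matrix

        bs = basis_matrix(reciprocal_of(cell))
        f1 = np.array(net.hkl_short, dtype=float) @ bs
        f2 = np.array(net.hkl_long, dtype=float) @ bs
        cstar = bs[2]
        n = np.cross(f1, f2)
        n /= np.linalg.norm(n)
        zeta = cstar @ n
        if zeta < 0:
            cstar, zeta = -cstar, -zeta
        A = np.array([f1, f2]).T
        xi, eta = np.linalg.lstsq(A, cstar - zeta * n, rcond=None)[0]
        rebuilt = direct_of(build_candidate_cell(frame, xi, eta, cell.volume))
        assert cells_equivalent(rebuilt, cell, tol_len=1e-6, tol_ang=1e-4)[0]


class TestSelectInitialZone:
    def test_labelled_high_symmetry_wins(self):
        assert select_initial_zone(cupc_patterns()) == "7"

    def test_fallback_to_next_symmetry(self):
        six = [p for p in cupc_patterns() if p.pattern_id != "7"]
        assert select_initial_zone(six) == "4"

    def test_tetragonal_pattern_first(self):
        assert select_initial_zone(lysozyme_patterns()) == "1"

    def test_tie_breaks_on_longest_vectors(self):
        five = [p for p in cupc_patterns(labelled=False) if p.pattern_id not in ("4", "7")]
        assert select_initial_zone(five) == "5"


class TestSearchRoundTrip:
    def test_recovers_generating_cell(self, rng):
        cell = make_random_cell(rng, lo=6, hi=14)
        pats, truth = simulate_dataset(SimulationSpec(cell=cell, zones=5, max_index=2, seed=11))
        cfg = ScanConfig(v_max=1.3 * cell.volume, v_min=0.75 * cell.volume,
                         mode="3d", max_index=6, hkl_max=8, max_refine=10)
        res = search(pats, cfg)
        assert res.solutions
        assert cells_equivalent(res.solutions[0].reduced_cell, cell, 0.01, 1.0)[0]
        assert res.solutions[0].r < 1e-4

    def test_deterministic(self, rng):
        cell = make_random_cell(rng, lo=6, hi=14)
        pats, _ = simulate_dataset(SimulationSpec(cell=cell, zones=4, max_index=2, seed=2))
        cfg = ScanConfig(v_max=1.25 * cell.volume, v_min=0.8 * cell.volume,
                         mode="3d", max_index=5, hkl_max=8, max_refine=5)
        a = search(pats, cfg)
        b = search(pats, cfg)
        assert [s.r for s in a.solutions] == [s.r for s in b.solutions]
        assert [s.cell.parameters for s in a.solutions] == [s.cell.parameters for s in b.solutions]

    def test_no_solution_for_too_small_volume_range(self, rng):
        cell = make_random_cell(rng, lo=8, hi=14)
        pats, _ = simulate_dataset(SimulationSpec(cell=cell, zones=4, max_index=2, seed=4))
        cfg = ScanConfig(v_max=0.35 * cell.volume, v_min=0.2 * cell.volume,
                         mode="3d", max_index=5, hkl_max=8)
        res = search(pats, cfg)
        assert res.solutions == []

    def test_candidate_volume_within_layer_increment(self, rng):
        cell = make_random_cell(rng, lo=6, hi=12)
        pats, _ = simulate_dataset(SimulationSpec(cell=cell, zones=4, max_index=2, seed=9))
        cfg = ScanConfig(v_max=1.3 * cell.volume, v_min=0.8 * cell.volume,
                         mode="3d", max_index=5, hkl_max=8, refine=False)
        res = search(pats, cfg)
        layers = np.array(res.layers)
        for sol in res.solutions:
            assert np.min(np.abs(layers - sol.volume)) < 1e-6


class TestFomSurface:
    def test_argmax_matches_best_unrefined_candidate(self):
        pats = lysozyme_patterns()
        cfg = ScanConfig(v_max=300000.0, initial="1", keep_trace=True, refine=False)
        res = search(pats, cfg)
        ts, vs, grid = fom_surface(res.trace, "origin")
        i, j = np.unravel_index(np.argmax(grid), grid.shape)
        origin_sols = [s for s in res.solutions if s.plane == "origin"]
        assert origin_sols
        best = min(origin_sols, key=lambda s: s.r)
        assert grid[i, j] == pytest.approx(1.0 / best.r, rel=1e-9)
        assert vs[j] == pytest.approx(best.volume, rel=1e-9)

    def test_all_rejected_plane_is_zero(self):
        trace = [("x=0", 0.1, 0.0, 0.1, 500.0, None), ("x=0", 0.2, 0.0, 0.2, 500.0, None)]
        _, _, grid = fom_surface(trace, "x=0")
        assert np.all(grid == 0)

    def test_missing_trace_rejected(self):
        with pytest.raises(ValueError):
            fom_surface([], "x=0")
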