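"""Zone enumeration, zone nets, pattern indexing and the reliability index."""

import math

import numpy as np
import pytest

from zonecell.lattice import UnitCell, basis_matrix, reciprocal_of
from zonecell.patterns import ZonePattern, classify_metric_symmetry
from zonecell.synthetic import simulate_zone_pattern
from zonecell.zones import (
    CENTRING_CONDITIONS,
    MatchWeights,
    enumerate_zones,
    index_pattern,
    pattern_mismatch,
    reliability_index,
    rescore_with_mean_scale,
    zone_net,
)

from conftest import make_random_cell

CUPC = UnitCell(17.685, 25.918, 3.8330, 90, 95.05, 90)
GRGDS = UnitCell(28.6756, 4.4446, 19.466, 90.0, 105.47, 90.02)


class TestEnumerateZones:
    def test_count_max_index_one(self):
        # brute force: 26 non-zero triples in {-1,0,1}³, all coprime, /2 for ±
        assert len(enumerate_zones(1)) == 13

    def test_contains_high_index_zone(self):
        assert (3, 5, 6) in enumerate_zones(6)

    def test_all_coprime_unique_up_to_sign(self):
        zones = enumerate_zones(3)
        assert len(set(zones)) == len(zones)
        for u, v, w in zones:
            assert math.gcd(math.gcd(abs(u), abs(v)), abs(w)) == 1
            assert tuple(-x for x in (u, v, w)) not in zones

    def test_deterministic_order(self):
        zones = enumerate_zones(2)
        sums = [abs(u) + abs(v) + abs(w) for u, v, w in zones]
        assert sums == sorted(sums)


class TestZoneNet:
    def test_cubic_001(self):
        net = zone_net(UnitCell(10, 10, 10), (0, 0, 1))
        assert net.g_short == pytest.approx(0.1)
        assert net.g_long == pytest.approx(0.1)
        assert net.phi == pytest.approx(90.0)

    def test_c_centred_absences(self):
        # C-centring suppresses (100)/(010); the [001] net basis becomes {110, 1-10}
        net = zone_net(CUPC, (0, 0, 1), centring="C")
        hkls = {tuple(abs(x) for x in net.hkl_short), tuple(abs(x) for x in net.hkl_long)}
        assert hkls == {(1, 1, 0)}
        assert 1 / net.g_short == pytest.approx(14.57, abs=0.01)

    def test_primitive_001_smaller_net(self):
        net = zone_net(CUPC, (0, 0, 1), centring="P")
        hkls = {tuple(abs(x) for x in net.hkl_short), tuple(abs(x) for x in net.hkl_long)}
        assert hkls == {(1, 0, 0), (0, 1, 0)}

    def test_brute_force_oracle(self, rng):
        """The net pair equals an exhaustive scan for the shortest reduced pair."""
        for _ in range(20):
            cell = make_random_cell(rng)
            zones = enumerate_zones(2)
            uvw = zones[rng.integers(len(zones))]
            net = zone_net(cell, uvw, hkl_max=6)
            bstar = basis_matrix(reciprocal_of(cell))
            best = []
            rng6 = range(-6, 7)
            for h in rng6:
                for k in rng6:
                    for l in rng6:
                        if (h, k, l) == (0, 0, 0):
                            continue
                        if h * uvw[0] + k * uvw[1] + l * uvw[2] != 0:
                            continue
                        best.append((np.linalg.norm(np.array([h, k, l]) @ bstar), (h, k, l)))
            best.sort()
            shortest = best[0]
            second = next(b for b in best[1:] if np.any(np.cross(shortest[1], b[1])))
            assert net.g_short == pytest.approx(shortest[0], rel=1e-9)
            assert net.g_long == pytest.approx(second[0], rel=1e-9)

    def test_zone_law_holds(self):
        net = zone_net(CUPC, (1, 0, 4), centring="C")
        for hkl in (net.hkl_short, net.hkl_long):
            assert hkl[0] * 1 + hkl[1] * 0 + hkl[2] * 4 == 0

    def test_non_coprime_rejected(self):
        with pytest.raises(ValueError):
            zone_net(CUPC, (2, 0, 2))


class TestPatternMismatch:
    def test_perfect_match(self):
        net = zone_net(UnitCell(10, 10, 10), (0, 0, 1))
        p = ZonePattern("x", 10.0, 10.0, 90.0)
        er, ea, es, t = pattern_mismatch(p, net, mean_scale=1.0)
        assert (er, ea, es, t) == pytest.approx((0, 0, 0, 0), abs=1e-12)

    def test_ratio_mismatch_normalization(self):
        # a ratio mismatch equal to w1 contributes exactly 1 to T_p
        net = zone_net(UnitCell(10, 10, 10), (0, 0, 1))
        p = ZonePattern("x", 10.0, 10.0 / 1.008, 90.0)
        er, ea, es, t = pattern_mismatch(p, net)
        assert er == pytest.approx(0.008, rel=1e-9)
        assert t == pytest.approx(1.0, rel=1e-9)

    def test_angle_mismatch_is_relative(self):
        net = zone_net(UnitCell(10, 10, 10), (0, 0, 1))
        p = ZonePattern("x", 10.0, 10.0, 89.4)
        er, ea, es, t = pattern_mismatch(p, net)
        assert ea == pytest.approx(0.6 / 90.0, rel=1e-6)
        assert t == pytest.approx((0.6 / 90.0) / 0.006, rel=1e-6)  # 1.111


class TestIndexPattern:
    def test_published_cupc_row(self):
        # (12.76, 2.97, 89.4) indexes as the {020, 40-1} pair of a [104]-type zone
        res = index_pattern(ZonePattern("4", 12.76, 2.97, 89.4), CUPC, centring="C")
        assert tuple(abs(x) for x in res.uvw) == (1, 0, 4)
        assert tuple(abs(x) for x in res.hkl_short) == (0, 2, 0)
        assert tuple(abs(x) for x in res.hkl_long) == (4, 0, 1)
        assert res.accepted

    def test_published_grgds_row(self):
        res = index_pattern(ZonePattern("1", 13.82, 4.39, 80.9), GRGDS, centring="C")
        assert tuple(abs(x) for x in res.uvw) == (0, 0, 1)
        assert {tuple(abs(x) for x in res.hkl_short), tuple(abs(x) for x in res.hkl_long)} == {
            (2, 0, 0), (1, 1, 0)}
        assert res.accepted

    def test_synthetic_round_trip(self, rng):
        cell = make_random_cell(rng)
        for uvw in [(0, 0, 1), (1, 1, 0), (2, -1, 1), (1, 2, 3), (3, 1, -2)]:
            pat = simulate_zone_pattern(cell, uvw)
            res = index_pattern(pat, cell, max_index=4, hkl_max=8)
            assert res.uvw in (uvw, tuple(-x for x in uvw))
            assert res.t_p < 1e-6
            assert res.accepted


class TestReliability:
    def _result(self, pid, er=0.0, ea=0.0, s=1.0):
        from zonecell.zones import IndexingResult

        return IndexingResult(pid, (0, 0, 1), (1, 0, 0), (0, 1, 0), er, ea, 0.0, s,
                              er / 0.008 + ea / 0.006, True)

    def test_zero_for_perfect(self):
        assert reliability_index([self._result("a"), self._result("b")]) == 0.0

    def test_mean_of_scores(self):
        results = [self._result("a", er=0.0016), self._result("b", er=0.0032)]
        # T_p = 0.2 and 0.4 under w1 = 0.008
        assert reliability_index(results) == pytest.approx(0.3)

    def test_global_scale_invariance(self):
        base = [self._result("a", er=0.001, s=1.0), self._result("b", er=0.002, s=1.01)]
        scaled = [self._result("a", er=0.001, s=1.1), self._result("b", er=0.002, s=1.111)]
        assert reliability_index(base) == pytest.approx(reliability_index(scaled), rel=1e-9)

    def test_rejected_input_refused(self):
        bad = self._result("a", er=0.2)
        object.__setattr__(bad, "accepted", False)
        with pytest.raises(ValueError):
            reliability_index([bad])

    def test_two_pass_scale_gating(self):
        # widely different per-pattern scales are caught on the second pass
        results = [self._result("a", s=1.0), self._result("b", s=1.2)]
        _, rescored = rescore_with_mean_scale(results)
        assert not all(r.accepted for r in rescored)


class TestCentringConditions:
    @pytest.mark.parametrize(
        "centring, allowed, forbidden",
        [
            ("A", (0, 2, 2), (0, 1, 2)),
            ("B", (1, 0, 1), (1, 0, 2)),
            ("C", (1, 1, 0), (1, 0, 0)),
            ("I", (1, 1, 2), (1, 1, 1)),
            ("F", (1, 1, 1), (1, 1, 2)),
        ],
    )
    def test_rules(self, centring, allowed, forbidden):
        cond = CENTRING_CONDITIONS[centring]
        h, k, l = (np.array([x]) for x in allowed)
        assert cond(h, k, l).all()
        h, k, l = (np.array([x]) for x in forbidden)
        assert not cond(h, k, l).any()
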