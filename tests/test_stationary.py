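"""Stationary analysis: graphs, RSP/SSP locations and stress ranges."""

import math

import numpy as np
import pytest

import pldesys as pl
from conftest import (
    PAR,
    RSP_TABLE,
    THETA,
    quadratic_roots_n_equals_theta,
)


class TestTransitionGraph:
    @pytest.mark.parametrize(
        "R, sink", [(0.0, (0, 2, 0)), (1.5, (1, 1, 1)), (9.0, (1, 0, 1))]
    )
    def test_unique_sink(self, p53, R, sink):
        tg = pl.transition_graph(p53, R)
        assert [s.ranks for s in tg.sinks] == [sink]

    def test_closed_sequence_at_mid_stress(self, p53):
        tg = pl.transition_graph(p53, 1.5)
        assert len(tg.cycles) >= 1

    def test_out_degree_at_most_one(self, p53):
        tg = pl.transition_graph(p53, 1.5)
        assert max(d for _, d in tg.graph.out_degree) <= 1

    @pytest.mark.parametrize("R", [0.0, 1.5, 9.0])
    def test_sinks_equal_rsp_set(self, p53, R):
        tg = pl.transition_graph(p53, R)
        rsps = pl.find_rsps(p53, R)
        assert {s.ranks for s in tg.sinks} == {sp.domain.ranks for sp in rsps}

    def test_cycles_disjoint_from_sinks(self, p53):
        tg = pl.transition_graph(p53, 1.5)
        in_cycles = {d.ranks for cyc in tg.cycles for d in cyc}
        assert in_cycles.isdisjoint({s.ranks for s in tg.sinks})


class TestRegularStationaryPoints:
    @pytest.mark.parametrize("R", sorted(RSP_TABLE))
    def test_exactly_one_rsp_at_printed_location(self, p53, R):
        ranks, printed = RSP_TABLE[R]
        rsps = pl.find_rsps(p53, R)
        assert len(rsps) == 1
        sp = rsps[0]
        assert sp.domain.ranks == ranks and sp.stability == "stable"
        got = p53.state_array(sp.location)
        assert np.max(np.abs(got - np.array(printed, float))) < 1.0

    def test_no_rsp_in_the_gap(self, p53):
        """Between the resting and mid-stress windows no focal point is its
        own stationary point; only the singular cycle remains."""
        assert pl.find_rsps(p53, 0.9) == []

    @pytest.mark.parametrize(
        "ranks, lo, hi",
        [
            ((0, 2, 0), 0.0, 0.8635),
            ((1, 1, 1), 1.0322, 1.9154),
            ((1, 0, 1), 1.9154, math.inf),
        ],
    )
    def test_existence_ranges_to_four_decimals(self, p53, ranks, lo, hi):
        ivs = pl.rsp_existence_range(p53, p53.domain(ranks))
        assert len(ivs) == 1
        got_lo, got_hi = ivs[0].rounded(4)
        assert got_lo == pytest.approx(lo, abs=5e-5)
        if math.isinf(hi):
            assert math.isinf(got_hi)
        else:
            assert got_hi == pytest.approx(hi, abs=5e-5)

    def test_bisection_agrees_with_quadratic_roots(self, p53):
        """Numeric endpoints vs the closed-form roots of the focal-N
        condition (independent oracle)."""
        # {020}: k1*=k10, p2*=p20, boundary where focal N = theta_N2
        r020 = quadratic_roots_n_equals_theta(THETA["N2"], PAR["k10"], PAR["p20"])
        hi020 = max(r020)
        iv = pl.rsp_existence_range(p53, p53.domain((0, 2, 0)))[0]
        assert iv.hi == pytest.approx(hi020, abs=1e-4)
        # {111}: k1*=k10-k11, p2*=p20+p21, boundaries at theta_N2 / theta_N1
        k1s, p2s = PAR["k10"] - PAR["k11"], PAR["p20"] + PAR["p21"]
        lo111 = max(quadratic_roots_n_equals_theta(THETA["N2"], k1s, p2s))
        hi111 = max(quadratic_roots_n_equals_theta(THETA["N1"], k1s, p2s))
        iv = pl.rsp_existence_range(p53, p53.domain((1, 1, 1)))[0]
        assert iv.lo == pytest.approx(lo111, abs=1e-4)
        assert iv.hi == pytest.approx(hi111, abs=1e-4)

    def test_rsp_windows_pairwise_disjoint(self, p53):
        ivs = []
        for dom in p53.all_domains():
            ivs.extend(pl.rsp_existence_range(p53, dom, r_max=12.0))
        for r in np.arange(0.0, 12.0, 0.05):
            assert sum(iv.contains(float(r)) for iv in ivs) <= 1


class TestDeltaRegions:
    def test_contains_worked_example_region(self, p53, ssp1_region):
        assert ssp1_region.describe(p53) == "Delta(theta_P, M, theta_N2, T<theta_T)"

    def test_one_pin_per_variable(self, regions):
        for region in regions:
            pvars = [v for v, _ in region.pinned]
            assert len(pvars) == len(set(pvars))
        # pinning both N thresholds at once never appears
        assert not any(
            {("N", "theta_N1"), ("N", "theta_N2")} <= set(r.pinned) for r in regions
        )

    def test_count_matches_brute_force_enumeration(self, p53, regions):
        """Combinatorial oracle: sum over pin patterns of the side
        assignments of the unpinned thresholded variables."""
        sizes = {"P": 1, "N": 2, "T": 1}  # thresholds per variable
        total = 0
        import itertools

        for pins in itertools.product([0, 1], [0, 1, 2], [0, 1]):
            if not any(pins):
                continue
            free = 1
            for v, p in zip(("P", "N", "T"), pins):
                if p == 0:
                    free *= sizes[v] + 1
            total += free
        assert len(regions) == total

    def test_single_pin_region_count(self, p53, regions):
        singles = [r for r in regions if len(r.pinned) == 1]
        # tP: 3*2 N,T assignments; tN1/tN2: 2*2 each; tT: 2*3
        assert len(singles) == 6 + 4 + 4 + 6


class TestSingularStationaryPoints:
    def test_worked_example_at_r2(self, p53, ssp1_region):
        ssp = pl.find_ssp(p53, ssp1_region, 2.0)
        assert ssp is not None
        assert ssp.singular_z["Z_N2"] == pytest.approx(0.3224, abs=5e-5)
        assert ssp.singular_z["Z_P"] == pytest.approx(0.084, abs=5e-4)
        assert ssp.location["P"] == THETA["P"]
        assert ssp.location["N"] == THETA["N2"]

    def test_below_window_no_ssp(self, p53, ssp1_region):
        assert pl.find_ssp(p53, ssp1_region, 0.5) is None

    def test_upper_region_holds_ssp_at_r1(self, p53, ssp2_region):
        ssp = pl.find_ssp(p53, ssp2_region, 1.0)
        assert ssp is not None
        assert ssp.location["T"] > THETA["T"]

    def test_singular_z_polynomial_printed_coefficients(self, p53, ssp1_region):
        c = pl.singular_value_polynomial(p53, ssp1_region, "Z_P")
        assert round(c[2], 4) == 0.0047
        assert round(c[1], 4) == 0.0603
        assert round(c[0], 4) == -0.0555

    def test_critical_z_for_pten_threshold(self, p53, ssp1_region):
        name, z = pl.side_condition_critical_z(p53, ssp1_region, "theta_T")
        assert name == "Z_P"
        assert z == pytest.approx((PAR["d3"] * THETA["T"] - PAR["p30"]) / PAR["p31"])
        assert round(z, 4) == 0.6858

    def test_admissibility_window_of_singular_zp(self, p53, ssp1_region):
        ivs = pl.singular_admissibility_range(p53, ssp1_region, "Z_P", r_max=12.0)
        assert len(ivs) == 1
        lo, hi = ivs[0].rounded(4)
        assert lo == pytest.approx(0.8635, abs=5e-5)
        assert hi == pytest.approx(9.9091, abs=5e-5)

    @pytest.mark.parametrize(
        "region_fixture, lo, hi",
        [("ssp1_region", 0.8635, 7.7038), ("ssp2_region", 0.7059, 1.0322)],
    )
    def test_existence_ranges_to_four_decimals(self, p53, request,
                                               region_fixture, lo, hi):
        region = request.getfixturevalue(region_fixture)
        ivs = pl.ssp_existence_range(p53, region, r_max=10.0)
        assert len(ivs) == 1
        got_lo, got_hi = ivs[0].rounded(4)
        assert got_lo == pytest.approx(lo, abs=5e-5)
        assert got_hi == pytest.approx(hi, abs=5e-5)

    def test_endpoints_agree_with_quadratic_oracle(self, p53, ssp1_region,
                                                   ssp2_region):
        """Existence boundaries vs closed-form roots: Z_P(R) = 0 at the lower
        bound of the low-PTEN region; Z_P(R) = critical value at its upper
        bound and at the high-PTEN region's lower bound."""
        z_crit = (PAR["d3"] * THETA["T"] - PAR["p30"]) / PAR["p31"]

        def roots(k1, target):
            d2, tN2 = PAR["d2"], THETA["N2"]
            a = tN2 * d2**2
            b = tN2 * (2 * d2**2 + d2 * k1)
            c = tN2 * (d2**2 + d2 * k1) - k1 * PAR["p20"] - target * k1 * PAR["p21"]
            return max(np.roots([a, b, c]))

        iv1 = pl.ssp_existence_range(p53, ssp1_region, r_max=10.0)[0]
        assert iv1.lo == pytest.approx(roots(PAR["k10"], 0.0), abs=1e-4)
        assert iv1.hi == pytest.approx(roots(PAR["k10"], z_crit), abs=1e-4)
        iv2 = pl.ssp_existence_range(p53, ssp2_region, r_max=10.0)[0]
        k1s = PAR["k10"] - PAR["k11"]
        assert iv2.lo == pytest.approx(roots(k1s, z_crit), abs=1e-4)
        assert iv2.hi == pytest.approx(roots(k1s, 1.0), abs=1e-4)

    def test_triple_crossing_reports_procedural_result(self, p53, triple_region):
        """The three-threshold face is solvable and yields a bounded window
        (the procedure pins the p53 switching value via the PTEN equation,
        leaving the transport switching value to bound the window)."""
        ssp = pl.find_ssp(p53, triple_region, 2.0)
        assert ssp is not None
        assert set(ssp.singular_z) == {"Z_P", "Z_N2", "Z_T"}
        assert ssp.singular_z["Z_P"] == pytest.approx(0.6858, abs=5e-5)
        ivs = pl.ssp_existence_range(p53, triple_region, r_max=10.0)
        assert len(ivs) == 1
        lo, hi = ivs[0].rounded(4)
        assert 0.70 <= lo <= 0.71
        assert 7.70 <= hi <= 7.71


class TestStability:
    def test_low_pten_cycle_is_stable(self, p53, ssp1_region):
        ssp = pl.find_ssp(p53, ssp1_region, 3.0)
        verdict = pl.classify_ssp_stability(p53, ssp, 3.0, seed=1, t_end=1.5e6)
        assert verdict == "stable"

    def test_triple_crossing_point_is_not_stable(self, p53, triple_region):
        ssp = pl.find_ssp(p53, triple_region, 2.0)
        verdict = pl.classify_ssp_stability(p53, ssp, 2.0, seed=1, t_end=1.5e6)
        assert verdict == "unstable"

    def test_zero_radius_probe_stays_near_pinned_thresholds(self, p53, ssp1_region):
        """Launched exactly from the SSP, the orbit circulates tightly around
        the pinned threshold crossing: every recorded event sits on one of the
        pinned thresholds and the early excursion stays small."""
        ssp = pl.find_ssp(p53, ssp1_region, 3.0)
        traj = pl.simulate(p53, ssp.location, 3.0, 1e5)
        assert traj.events, "the binary flow must switch around the SSP"
        pinned = {t for _, t in ssp1_region.pinned}
        assert {e.threshold for e in traj.events[:10]} <= pinned
        early = traj.states[traj.times <= 2e4]
        p_col = early[:, p53.variable_index("P")]
        assert np.max(np.abs(p_col - ssp.location["P"])) < 0.05 * ssp.location["P"]
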