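"""Transition counting, condition summaries, rank-sum comparison."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from seamsta.caller import SegmentCall
from seamsta.fixtures import planted_rate_lattices
from seamsta.lattice import find_transitions, make_spec
from seamsta.pipeline import calls_from_lattice
from seamsta.stats import (
    MicrotubuleResult,
    StatsError,
    condition_summary,
    count_transitions,
    lateral_interaction_count,
    ranksum_test,
)


def seg(i, seams, n=13, s=3, nd=()):
    """Minimal determined (or partially ND) segment call."""
    types = np.full(n, "B", dtype="<U1")
    for c in seams:
        types[c] = "A"
    for c in nd:
        types[c] = "N"
    return SegmentCall(segment=i, z_range=(i * 160.0, (i + 1) * 160.0), N=n, S=s,
                       phases=np.zeros(n), coherences=np.ones(n),
                       contact_types=types)


class TestCountTransitions:
    def test_seam_offset_by_one(self):
        calls = [seg(0, {0}), seg(1, {0}), seg(2, {1})]
        out = count_transitions(calls)
        assert len(out) == 1
        assert out[0].kind == "seam-offset"
        assert out[0].between == (1, 2)

    def test_seam_count_change_bridged_over_nd(self):
        calls = [seg(0, {0, 1, 2, 3, 4}), seg(1, set(), nd=(2, 3)),
                 seg(2, {0, 2, 4})]
        out = count_transitions(calls)
        assert len(out) == 1
        assert out[0].kind == "seam-count"
        assert out[0].between == (0, 2)  # localized to the bridged interval

    def test_identical_segments_no_transitions(self):
        assert count_transitions([seg(i, {0}) for i in range(5)]) == []

    def test_ns_change_counted_once(self):
        calls = [seg(0, set(), n=13, s=4), seg(1, {0}, n=13, s=3)]
        out = count_transitions(calls)
        assert len(out) == 1 and out[0].kind == "N_S-change"

    def test_single_segment_empty(self):
        assert count_transitions([seg(0, {0})]) == []

    def test_wraparound_offset_detected(self):
        out = count_transitions([seg(0, {0}), seg(1, {12})])
        assert out[0].kind == "seam-offset"


class TestLateralInteractions:
    def test_two_13pf_segments(self):
        assert lateral_interaction_count([seg(0, {0}), seg(1, {0})]) == 26

    def test_empty(self):
        assert lateral_interaction_count([]) == 0

    def test_mixed_pf_counts(self):
        calls = [seg(i, {0}, n=13) for i in range(3)] + \
                [seg(i, {0}, n=14) for i in range(3, 5)]
        assert lateral_interaction_count(calls) == 3 * 13 + 2 * 14


def _uniform_condition(n_mt, total_len_um, n_transitions):
    """Microtubules of equal length; the first n_transitions carry one
    seam-offset transition each."""
    results = []
    length = total_len_um / n_mt
    for i in range(n_mt):
        if i < n_transitions:
            calls = [seg(0, {0}), seg(1, {1})]
        else:
            calls = [seg(0, {0}), seg(1, {0})]
        results.append(MicrotubuleResult.from_calls(f"MT{i}", length, calls))
    return results


class TestConditionSummary:
    def test_cytoplasmic_dmso_style_aggregate(self):
        """64 tubes over 67.4 um with 6 transitions -> 0.09 per um."""
        s = condition_summary(_uniform_condition(64, 67.4, 6))
        assert s.aggregate_frequency == pytest.approx(0.09, abs=0.005)

    def test_cytoplasmic_ran_style_aggregate(self):
        """15 tubes over 19.9 um with 2 transitions -> 0.10 per um."""
        s = condition_summary(_uniform_condition(15, 19.9, 2))
        assert s.aggregate_frequency == pytest.approx(0.10, abs=0.005)

    def test_zero_transition_condition(self):
        s = condition_summary(_uniform_condition(5, 5.0, 0))
        assert s.aggregate_frequency == 0.0
        assert s.per_mt_mean == 0.0 and s.per_mt_sd == 0.0

    def test_contact_totals_consistent(self):
        """A + B + ND always equals the lateral-interaction total."""
        lats = planted_rate_lattices(n_mt=6, length=800.0, seed=4)
        results = [MicrotubuleResult.from_calls(str(i), lat.length / 1000.0,
                                                calls_from_lattice(lat, 160.0))
                   for i, lat in enumerate(lats)]
        s = condition_summary(results)
        assert sum(s.counts.values()) == s.lateral_interactions
        assert s.lateral_interactions == s.n_segments * 13

    def test_percentages_sum_to_hundred(self):
        lats = planted_rate_lattices(n_mt=6, length=800.0, seed=4)
        results = [MicrotubuleResult.from_calls(str(i), lat.length / 1000.0,
                                                calls_from_lattice(lat, 160.0))
                   for i, lat in enumerate(lats)]
        s = condition_summary(results)
        assert sum(s.ns_percent.values()) == pytest.approx(100.0)
        assert sum(s.seam_number_percent.values()) == pytest.approx(100.0)
        assert sum(s.lattice_type_percent.values()) == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(StatsError):
            condition_summary([])


class TestPlantedRateRecovery:
    def test_condition_level_rate_recovery(self):
        """Segmented analysis of 20 simulated tubes recovers the planted
        transition rate within Poisson sampling error."""
        rate, n_mt, length = 0.25, 20, 1600.0
        lats = planted_rate_lattices(n_mt=n_mt, length=length,
                                     rate_per_um=rate, seed=3)
        results = [MicrotubuleResult.from_calls(str(i), lat.length / 1000.0,
                                                calls_from_lattice(lat, 160.0))
                   for i, lat in enumerate(lats)]
        s = condition_summary(results)
        expected = rate * n_mt * length / 1000.0
        assert abs(s.n_transitions - expected) <= 2.5 * np.sqrt(expected)

    def test_segment_counts_match_ground_truth_when_determined(self):
        """Where every segment is determined, the stats pipeline count equals
        the lattice-level transition scan."""
        lats = planted_rate_lattices(n_mt=10, length=1600.0, rate_per_um=0.1,
                                     seed=9)
        for lat in lats:
            calls = calls_from_lattice(lat, 160.0)
            if not all(c.determined for c in calls):
                continue
            assert len(count_transitions(calls)) == len(find_transitions(lat)[0])


def test_condition_panel_figure(tmp_path):
    """Bar-panel rendering of condition summaries writes a figure file."""
    from seamsta.stats import plot_condition_panels

    lats = planted_rate_lattices(n_mt=4, length=800.0, seed=1)
    results = [MicrotubuleResult.from_calls(str(i), lat.length / 1000.0,
                                            calls_from_lattice(lat, 160.0))
               for i, lat in enumerate(lats)]
    s = condition_summary(results, label="sim")
    out = tmp_path / "panels.png"
    fig = plot_condition_panels([s], path=out)
    assert out.exists() and out.stat().st_size > 0
    import matplotlib.pyplot as plt

    plt.close(fig)


class TestRankSum:
    def test_exact_small_sample(self):
        u, p = ranksum_test([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_exact_three_vs_three(self):
        u, p = ranksum_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        _, p = ranksum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 6)
            u, p = ranksum_test(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1.0, 1, 25)
        u, p = ranksum_test(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
        assert p == pytest.approx(float(ref.pvalue), rel=0.01)

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError):
            ranksum_test([], [1.0])
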