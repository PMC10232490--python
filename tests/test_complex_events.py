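"""Interleaving graph, oscillation counting and the component statistics."""

import itertools

import numpy as np
import pytest

from somascape.complex_events import (
    breakpoint_exponential_test,
    call_complex_events,
    chromosomal_enrichment_test,
    count_oscillations,
    detect_interleaved_clusters,
    fragment_joins_test,
)
from somascape.simulate import (
    generate_genome,
    simulate_chromothripsis_svs,
    simulate_cn_profile,
    simulate_svs,
)
from somascape.types import CnSegment, SvRecord


def sv(a, b, t="DEL", sample="S1", chrom="chr1"):
    return SvRecord(sample, chrom, a, chrom, b, t)


def seg_states(states, chrom="chr1", size=1_000_000):
    return [
        CnSegment("S1", chrom, i * size, (i + 1) * size, cn, cn // 2)
        for i, cn in enumerate(states)
    ]


def brute_force_components(svs):
    """O(n^2) reachability oracle over the interleaving relation."""
    n = len(svs)
    ivs = [(min(r.pos1, r.pos2), max(r.pos1, r.pos2)) for r in svs]

    def interleaves(i, j):
        (a1, a2), (b1, b2) = ivs[i], ivs[j]
        overlap = a1 < b2 and b1 < a2
        nested = (a1 <= b1 and b2 <= a2) or (b1 <= a1 and a2 <= b2)
        return overlap and not nested

    comp = list(range(n))
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(n), 2):
            if interleaves(i, j) and comp[i] != comp[j]:
                tgt = min(comp[i], comp[j])
                src = max(comp[i], comp[j])
                comp = [tgt if c == src else c for c in comp]
                changed = True
    sizes = sorted(
        (comp.count(c) for c in set(comp)), reverse=True
    )
    return sizes


class TestInterleavedClusters:
    def test_disjoint_svs_are_singletons(self):
        clusters = detect_interleaved_clusters([sv(100, 200), sv(1_000, 2_000)])
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_chain_of_twelve_matches_brute_force(self):
        svs = [sv(1_000 * i, 1_000 * i + 1_500) for i in range(12)]
        clusters = detect_interleaved_clusters(svs)
        assert len(clusters[0]) == 12
        assert [len(c) for c in clusters] == brute_force_components(svs)

    def test_nested_intervals_not_connected(self):
        clusters = detect_interleaved_clusters([sv(100, 10_000), sv(500, 2_000)])
        assert sorted(len(c) for c in clusters) == [1, 1]

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            svs = []
            for _ in range(15):
                a = int(rng.integers(1, 100_000))
                b = a + int(rng.integers(100, 50_000))
                svs.append(sv(a, b))
            got = sorted((len(c) for c in detect_interleaved_clusters(svs)),
                         reverse=True)
            assert got == brute_force_components(svs)


class TestOscillations:
    def test_constant_states(self):
        assert count_oscillations(seg_states([2, 2, 2])) == (0, 0)

    def test_alternating_two_states(self):
        assert count_oscillations(seg_states([2, 3, 2, 3, 2, 3, 2])) == (6, 6)

    def test_three_state_run(self):
        two, three = count_oscillations(seg_states([1, 2, 3, 2, 1]))
        assert two == 2
        assert three == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            count_oscillations([])


class TestExponentialTest:
    def test_calibrated_under_exponential_spacing(self):
        rng = np.random.default_rng(5)
        pvals = [
            breakpoint_exponential_test(np.cumsum(rng.exponential(1_000, 60)))
            for _ in range(200)
        ]
        from scipy import stats

        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_regular_spacing_rejected(self):
        p = breakpoint_exponential_test(np.arange(50) * 1_000)
        assert p < 0.01

    def test_too_few_breakpoints_not_testable(self):
        assert breakpoint_exponential_test([100, 200]) is None


class TestEnrichmentTest:
    def test_concentrated_breakpoints_significant(self):
        p = chromosomal_enrichment_test(100, 100, 10_000_000, 100_000_000)
        assert p < 1e-10

    def test_proportional_allocation_not_significant(self):
        p = chromosomal_enrichment_test(10, 100, 10_000_000, 100_000_000)
        assert p > 0.3

    def test_zero_breakpoints(self):
        assert chromosomal_enrichment_test(0, 50, 10_000_000, 100_000_000) == 1.0


class TestFragmentJoins:
    def test_equal_counts_give_p_one(self):
        assert fragment_joins_test([5, 5, 5, 5]) >= 0.99

    def test_one_sided_counts_reject(self):
        assert fragment_joins_test([20, 0, 0, 0]) < 0.001

    def test_single_sv_monte_carlo_valid(self):
        p = fragment_joins_test([1, 0, 0, 0], seed=1)
        assert 0 <= p <= 1


class TestCalling:
    def test_quiet_chromosome_not_called(self, toy_genome):
        svs = {"S1": [sv(100, 5_000), sv(2_000_000, 2_005_000)]}
        segs = {"S1": seg_states([2] * 20)}
        calls, flags = call_complex_events(svs, segs, toy_genome)
        assert not any(c.called for c in calls)
        assert not flags["S1"]

    def test_constructed_chromothripsis_called_under_a(self):
        genome = generate_genome(2, 100_000_000, seed=31)
        svs = simulate_chromothripsis_svs(genome, "chr1", n_sv=40,
                                          centre=10_000_000, seed=1)
        states = [[2, 3][i % 2] for i in range(13)]
        segs = [
            CnSegment("S1", "chr1", s.start, s.end, s.total_cn, s.minor_cn)
            for s in seg_states(states, size=100_000_000 // 13)
        ]
        calls, flags = call_complex_events({"S1": svs}, {"S1": segs}, genome, seed=0)
        called = [c for c in calls if c.called]
        assert len(called) == 1
        assert called[0].criterion == "A"
        assert flags["S1"]

    def test_large_cluster_regular_cn_called_under_b_only(self):
        genome = generate_genome(2, 100_000_000, seed=32)
        svs = simulate_chromothripsis_svs(genome, "chr1", n_sv=35,
                                          centre=20_000_000, seed=2)
        segs = seg_states([2] * 10, size=10_000_000)
        calls, flags = call_complex_events({"S1": svs}, {"S1": segs}, genome, seed=0)
        called = [c for c in calls if c.called]
        assert len(called) == 1
        assert called[0].criterion == "B"

    def test_more_than_one_event_option(self, toy_genome):
        svs = {"S1": simulate_chromothripsis_svs(toy_genome, "chr1", 35,
                                                 centre=5_000_000, seed=3)}
        segs = {"S1": []}
        _, strict = call_complex_events(svs, segs, toy_genome, min_events=2, seed=0)
        _, loose = call_complex_events(svs, segs, toy_genome, min_events=1, seed=0)
        assert loose["S1"] and not strict["S1"]

    def test_monotone_in_added_interleaved_svs(self):
        genome = generate_genome(1, 100_000_000, seed=33)
        base = simulate_chromothripsis_svs(genome, "chr1", 35, centre=10_000_000,
                                           seed=4)
        more = base + simulate_chromothripsis_svs(genome, "chr1", 10,
                                                  centre=10_500_000, seed=5)
        segs = {"S1": seg_states([2] * 10, size=10_000_000)}
        _, f1 = call_complex_events({"S1": base}, segs, genome, seed=0)
        _, f2 = call_complex_events({"S1": more}, segs, genome, seed=0)
        if f1["S1"]:
            assert f2["S1"]

    def test_false_rate_on_quiet_genomes(self):
        genome = generate_genome(2, 100_000_000, seed=34)
        n_false = 0
        for rep in range(30):
            svs = simulate_svs(genome, np.full(32, 1 / 32), 20, seed=rep)
            segs = simulate_cn_profile(genome, 2.0, 0.0, seed=rep)
            by = {}
            for r in svs:
                by.setdefault(r.sample_id, []).append(r)
            _, flags = call_complex_events(by, {"S1": segs}, genome, seed=rep)
            n_false += any(flags.values())
        assert n_false / 30 <= 0.05
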