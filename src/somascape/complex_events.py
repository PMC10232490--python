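"""Chromothripsis-like complex event calling.

Per sample and chromosome, intra-chromosomal SVs are treated as
intervals; two SVs interleave when their intervals overlap without one
containing the other, and connected components of the interleaving
graph are clusters. Copy-number oscillation runs, a chromosomal
breakpoint-enrichment binomial test, an exponential goodness-of-fit
test on inter-breakpoint distances, and a fragment-joins multinomial
test complete the evidence. A chromosome is called complex under

* criterion A: interleaved cluster > 10 SVs, oscillations between two
  or three copy states > 6, enrichment q < 0.05, exponential q < 0.05
  and fragment-joins q < 0.2; or
* criterion B: interleaved cluster > 30 SVs and exponential q < 0.05.

The exponential test in the calling step runs on the chromosome's full
breakpoint spacing anchored at the chromosome ends, so a significant
(small) q flags breakpoints that are locally clustered rather than
dispersed, which is the chromothripsis expectation.

A sample is a complex genome when it carries at least ``min_events``
called events (default 1; the stricter "more than one" reading is
available via the argument).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .types import ComplexEventCall, CnSegment, GenomeModel, SvRecord

__all__ = [
    "detect_interleaved_clusters",
    "count_oscillations",
    "breakpoint_exponential_test",
    "chromosomal_enrichment_test",
    "fragment_joins_test",
    "call_complex_events",
]


def detect_interleaved_clusters(svs: Sequence[SvRecord]) -> list[list[SvRecord]]:
    """Connected components of the interleaving graph of one chromosome's SVs.

    Two SVs are connected iff their intervals overlap without one
    containing the other (nested pairs are not connected). Returns
    clusters sorted by decreasing size.
    """
    intra = [r for r in svs if r.sv_type != "TRA"]
    n = len(intra)
    ivs = [(min(r.pos1, r.pos2), max(r.pos1, r.pos2)) for r in intra]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        a1, a2 = ivs[i]
        for j in range(i + 1, n):
            b1, b2 = ivs[j]
            overlap = a1 < b2 and b1 < a2
            nested = (a1 <= b1 and b2 <= a2) or (b1 <= a1 and a2 <= b2)
            if overlap and not nested:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intra[i])
    return sorted(groups.values(), key=len, reverse=True)


def count_oscillations(segments: Sequence[CnSegment]) -> tuple[int, int]:
    """Longest oscillation runs of a chromosome's ordered CN states.

    Returns ``(two_state, three_state)``: the maximum number of
    consecutive alternation steps (adjacent states differing) confined
    to at most 2, respectively at most 3, distinct total copy numbers.
    """
    if not segments:
        raise ValueError("empty segment list")
    states = [s.total_cn for s in sorted(segments, key=lambda s: s.start)]

    def longest(max_states: int) -> int:
        best = 0
        n = len(states)
        for i in range(n):
            seen = {states[i]}
            for j in range(i + 1, n):
                if states[j] == states[j - 1]:
                    break
                seen.add(states[j])
                if len(seen) > max_states:
                    break
                best = max(best, j - i)
        return best

    return longest(2), longest(3)


def breakpoint_exponential_test(positions: Sequence[int]) -> Optional[float]:
    """Exponential goodness-of-fit p-value for inter-breakpoint distances.

    One-sample Kolmogorov-Smirnov with the rate estimated from the data
    (Lilliefors correction, so the p-value is calibrated under the
    estimated-parameter null). Returns None for fewer than 3
    breakpoints (not testable).
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    if pos.size < 3:
        return None
    dists = np.diff(pos)
    dists = dists[dists > 0]
    if dists.size < 2:
        return None
    _, p = lilliefors(dists, dist="exp", pvalmethod="table")
    return float(p)


def chromosomal_enrichment_test(
    chrom_count: int, total_count: int, chrom_length: int, genome_length: int
) -> float:
    """Binomial upper-tail test of a chromosome's breakpoint count.

    Success probability = chromosome length / genome length.
    """
    if chrom_count < 0 or total_count < chrom_count:
        raise ValueError("invalid breakpoint counts")
    if total_count == 0 or chrom_count == 0:
        return 1.0
    p0 = chrom_length / genome_length
    return float(stats.binom.sf(chrom_count - 1, total_count, p0))


def fragment_joins_test(
    join_counts: Sequence[int], seed: int = 0, n_sim: int = 2000
) -> float:
    """Multinomial goodness-of-fit of the four join types vs equal proportions.

    Join types are {deletion-like, duplication-like, head-to-head
    inversion, tail-to-tail inversion}. Chi-square when all expected
    counts are >= 5, otherwise a seeded Monte-Carlo multinomial
    simulation of the chi-square statistic.
    """
    k = np.asarray(join_counts, dtype=float)
    if k.size != 4 or (k < 0).any():
        raise ValueError("need 4 non-negative join counts")
    n = k.sum()
    if n == 0:
        return 1.0
    expected = np.full(4, n / 4.0)
    chi2 = float(((k - expected) ** 2 / expected).sum())
    if expected.min() >= 5:
        return float(stats.chi2.sf(chi2, df=3))
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(int(n), np.full(4, 0.25), size=n_sim)
    sim_chi2 = ((sims - expected) ** 2 / expected).sum(axis=1)
    return float((np.sum(sim_chi2 >= chi2 - 1e-12) + 1) / (n_sim + 1))


def _join_counts(cluster: Sequence[SvRecord]) -> list[int]:
    # SvRecord carries no inversion orientation; inversions are split
    # evenly between the head-to-head and tail-to-tail categories.
    dels = sum(r.sv_type == "DEL" for r in cluster)
    dups = sum(r.sv_type == "DUP" for r in cluster)
    invs = sum(r.sv_type == "INV" for r in cluster)
    return [dels, dups, -(-invs // 2), invs // 2]


def call_complex_events(
    svs_by_sample: dict,
    segments_by_sample: dict,
    genome: GenomeModel,
    min_interleaved: int = 10,
    min_oscillations: int = 6,
    q_enrichment_cut: float = 0.05,
    q_exponential_cut: float = 0.05,
    q_joins_cut: float = 0.2,
    min_interleaved_b: int = 30,
    min_events: int = 1,
    seed: int = 0,
) -> tuple[list[ComplexEventCall], dict]:
    """Call complex events cohort-wide and flag complex-genome samples.

    All component p-values are Benjamini-Hochberg adjusted within their
    own family across the cohort (enrichment across sample-chromosomes,
    exponential across tested regions, joins across clusters) before
    the criterion thresholds are applied.
    """
    rows = []  # evidence per (sample, chromosome)
    for sid, svs in svs_by_sample.items():
        segments = segments_by_sample.get(sid, [])
        breakends: dict = {}
        for r in svs:
            breakends.setdefault(r.chrom1, []).append(r.pos1)
            breakends.setdefault(r.chrom2, []).append(r.pos2)
        total_bp = sum(len(v) for v in breakends.values())
        for chrom in genome.names:
            chrom_svs = [
                r for r in svs
                if r.chrom1 == chrom and r.sv_type != "TRA"
            ]
            if not chrom_svs:
                continue
            clusters = detect_interleaved_clusters(chrom_svs)
            cluster = clusters[0] if clusters else []
            n_int = len(cluster)
            if cluster:
                lo = min(min(r.pos1, r.pos2) for r in cluster)
                hi = max(max(r.pos1, r.pos2) for r in cluster)
            else:
                lo = hi = 0
            # chromosome-wide spacing family, anchored at the chromosome
            # ends: a localized breakpoint cluster then deviates from the
            # exponential expectation, while dispersed breakpoints fit it
            chrom_bp = sorted(breakends.get(chrom, []))
            region_bp = [0, *chrom_bp, genome.length(chrom)]
            chrom_segs = [s for s in segments if s.chrom == chrom]
            if chrom_segs:
                osc2, osc3 = count_oscillations(chrom_segs)
            else:
                osc2 = osc3 = 0
            p_exp = breakpoint_exponential_test(region_bp)
            p_enr = chromosomal_enrichment_test(
                len(breakends.get(chrom, [])), total_bp,
                genome.length(chrom), genome.total_length,
            )
            p_join = fragment_joins_test(_join_counts(cluster), seed=seed) if cluster else None
            rows.append(
                dict(sample=sid, chrom=chrom, region=(lo, hi), n_int=n_int,
                     osc2=osc2, osc3=osc3, p_enr=p_enr, p_exp=p_exp, p_join=p_join)
            )

    def bh(values):
        idx = [i for i, v in enumerate(values) if v is not None]
        out = [np.nan] * len(values)
        if idx:
            q = multipletests([values[i] for i in idx], method="fdr_bh")[1]
            for i, qi in zip(idx, q):
                out[i] = float(qi)
        return out

    q_enr = bh([r["p_enr"] for r in rows])
    q_exp = bh([r["p_exp"] for r in rows])
    q_join = bh([r["p_join"] for r in rows])

    calls: list[ComplexEventCall] = []
    flags: dict = {sid: False for sid in svs_by_sample}
    n_events: dict = {sid: 0 for sid in svs_by_sample}
    for r, qe, qx, qj in zip(rows, q_enr, q_exp, q_join):
        crit_a = (
            r["n_int"] > min_interleaved
            and r["osc3"] > min_oscillations
            and not np.isnan(qe) and qe < q_enrichment_cut
            and not np.isnan(qx) and qx < q_exponential_cut
            and not np.isnan(qj) and qj < q_joins_cut
        )
        crit_b = (
            r["n_int"] > min_interleaved_b
            and not np.isnan(qx) and qx < q_exponential_cut
        )
        called = crit_a or crit_b
        criterion = "A" if crit_a else ("B" if crit_b else None)
        calls.append(
            ComplexEventCall(
                r["sample"], r["chrom"], r["region"], r["n_int"], r["osc2"],
                r["osc3"], qe, qx, qj, criterion, called,
            )
        )
        if called:
            n_events[r["sample"]] += 1
    for sid in flags:
        flags[sid] = n_events[sid] >= min_events
    return calls, flags
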