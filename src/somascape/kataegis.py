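"""Kataegis detection and APOBEC classification.

A sliding-window exact binomial test flags windows whose mutation count
exceeds what the chromosome-wide per-bp mutation rate predicts;
optionally, per-window trinucleotide composition is tested the same way
against the genome model's chromosome trinucleotide frequencies.
Window p-values are Benjamini-Hochberg adjusted per sample (pooled over
all windows of all chromosomes), significant windows are merged, and a
merged region is a kataegis locus when it holds at least ``min_mut``
mutations with mean inter-mutation distance at most ``max_imd``. Each
locus gets a hypermutation score (locus mutation density over the
chromosome's density) and an APOBEC score (fraction of member SNVs that
are C>T or C>G at TpCpW, i.e. TCA/TCT context); loci at or above the
APOBEC cutoff are classed APOBEC.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .constants import TRINUCLEOTIDES_32
from .types import GenomeModel, KataegisLocus, SnvRecord

__all__ = ["scan_windows", "call_kataegis_loci", "classify_apobec", "detect_kataegis"]

WINDOW_DEFAULT = 10_000
STEP_DEFAULT = 5_000
MIN_MUT_DEFAULT = 6
MAX_IMD_DEFAULT = 2_000
Q_CUT_DEFAULT = 0.05
APOBEC_CUTOFF_DEFAULT = 0.5

_APOBEC_CONTEXTS = ("TCA", "TCT")
_APOBEC_CLASSES = ("C>T", "C>G")


def _is_apobec(r: SnvRecord) -> bool:
    return r.subst_class in _APOBEC_CLASSES and r.context3 in _APOBEC_CONTEXTS


def scan_windows(
    snvs: Sequence[SnvRecord],
    genome: GenomeModel,
    window: int = WINDOW_DEFAULT,
    step: int = STEP_DEFAULT,
    trinucleotide_tests: bool = False,
) -> pd.DataFrame:
    """Per-window statistics for one sample (all chromosomes).

    For each window the exact binomial upper-tail p-value of its
    mutation count is computed under a per-bp rate equal to the sample's
    chromosome-wide rate. With ``trinucleotide_tests`` the proportion of
    each of the 32 trinucleotides within the window is also tested
    (binomial upper tail against the chromosome's trinucleotide
    frequency; minimum over trinucleotides reported as ``p_trinuc``).
    Windows with no mutations are retained with p = 1 so that the
    cohort-level BH adjustment sees the full family.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    samples = {r.sample_id for r in snvs}
    if len(samples) > 1:
        raise ValueError("scan_windows expects one sample's SNVs")
    frames = []
    for chrom, length, _ in genome.chromosomes:
        muts = sorted((r for r in snvs if r.chrom == chrom), key=lambda r: r.pos)
        positions = np.array([r.pos for r in muts], dtype=np.int64)
        n_chrom = positions.size
        starts = np.arange(0, max(length - window, 0) + 1, step, dtype=np.int64)
        if starts.size == 0:
            starts = np.array([0], dtype=np.int64)
        ends = np.minimum(starts + window, length)
        lo = np.searchsorted(positions, starts + 1, side="left")
        hi = np.searchsorted(positions, ends, side="right")
        counts = hi - lo
        rate = n_chrom / length
        # upper tail P(X >= k) for X ~ Binomial(window_bp, rate)
        pvals = stats.binom.sf(counts - 1, ends - starts, rate)
        pvals = np.where(counts == 0, 1.0, pvals)
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": ends,
                "n_mut": counts,
                "p_count": pvals,
            }
        )
        if trinucleotide_tests:
            freq = genome.trinucleotide_freq.loc[chrom]
            ctx = [r.context3 for r in muts]
            ctx_codes = np.array(
                [TRINUCLEOTIDES_32.index(c) for c in ctx], dtype=np.int64
            )
            p_tri = np.ones(starts.size)
            nz = np.flatnonzero(counts > 0)
            for wi in nz:
                codes = ctx_codes[lo[wi]: hi[wi]]
                k = np.bincount(codes, minlength=32)
                n = k.sum()
                p32 = stats.binom.sf(k - 1, n, freq.to_numpy())
                p_tri[wi] = float(p32.min())
            df["p_trinuc"] = p_tri
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def call_kataegis_loci(
    window_stats: pd.DataFrame,
    snvs: Sequence[SnvRecord],
    genome: GenomeModel,
    min_mut: int = MIN_MUT_DEFAULT,
    max_imd: float = MAX_IMD_DEFAULT,
    q_cut: float = Q_CUT_DEFAULT,
    apobec_cutoff: float = APOBEC_CUTOFF_DEFAULT,
) -> list[KataegisLocus]:
    """Call kataegis loci for one sample from its window scan.

    Window count p-values are BH-adjusted across all windows of the
    sample; overlapping significant windows are merged and a merged
    region becomes a locus iff it contains >= ``min_mut`` mutations
    whose mean inter-mutation distance is <= ``max_imd`` bp.
    """
    if window_stats.empty:
        return []
    sample_ids = {r.sample_id for r in snvs}
    sample_id = sample_ids.pop() if sample_ids else "NA"
    qvals = multipletests(window_stats["p_count"].to_numpy(), method="fdr_bh")[1]
    ws = window_stats.assign(q=qvals)
    sig = ws[(ws["q"] < q_cut) & (ws["n_mut"] > 0)]
    loci: list[KataegisLocus] = []
    by_chrom: dict = {}
    for r in snvs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, grp in sig.groupby("chrom", sort=False):
        muts = sorted(by_chrom.get(chrom, []), key=lambda r: r.pos)
        positions = np.array([m.pos for m in muts], dtype=np.int64)
        chrom_len = genome.length(chrom)
        chrom_density = max(len(muts), 1) / chrom_len
        grp = grp.sort_values("start")
        merged: list[list] = []
        for row in grp.itertuples(index=False):
            if merged and row.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], row.end)
                merged[-1][2] = min(merged[-1][2], row.q)
            else:
                merged.append([row.start, row.end, row.q])
        for start, end, q in merged:
            lo = np.searchsorted(positions, start + 1, side="left")
            hi = np.searchsorted(positions, end, side="right")
            members = muts[lo:hi]
            n = len(members)
            if n < min_mut:
                continue
            span = members[-1].pos - members[0].pos
            mean_imd = span / (n - 1)
            if mean_imd > max_imd:
                continue
            density = n / max(span, 1)
            apobec = sum(_is_apobec(m) for m in members) / n
            loci.append(
                KataegisLocus(
                    sample_id,
                    chrom,
                    int(members[0].pos),
                    int(members[-1].pos),
                    n,
                    float(density / chrom_density),
                    float(apobec),
                    float(q),
                    "APOBEC" if apobec >= apobec_cutoff else "non-APOBEC",
                )
            )
    return loci


def classify_apobec(
    members: Sequence[SnvRecord], cutoff: float = APOBEC_CUTOFF_DEFAULT
) -> tuple[float, str]:
    """APOBEC score and class for a locus's member mutations.

    Score = fraction of mutations that are C>T or C>G at TCA/TCT
    context; class is APOBEC iff score >= cutoff.
    """
    if not members:
        raise ValueError("empty locus")
    score = sum(_is_apobec(m) for m in members) / len(members)
    return score, "APOBEC" if score >= cutoff else "non-APOBEC"


def detect_kataegis(
    snvs_by_sample: dict,
    genome: GenomeModel,
    window: int = WINDOW_DEFAULT,
    step: int = STEP_DEFAULT,
    min_mut: int = MIN_MUT_DEFAULT,
    max_imd: float = MAX_IMD_DEFAULT,
    q_cut: float = Q_CUT_DEFAULT,
    apobec_cutoff: float = APOBEC_CUTOFF_DEFAULT,
) -> list[KataegisLocus]:
    """Scan and call kataegis for every sample in the cohort."""
    loci: list[KataegisLocus] = []
    for sid, snvs in snvs_by_sample.items():
        ws = scan_windows(snvs, genome, window=window, step=step)
        loci.extend(
            call_kataegis_loci(
                ws, snvs, genome, min_mut=min_mut, max_imd=max_imd,
                q_cut=q_cut, apobec_cutoff=apobec_cutoff,
            )
        )
    return loci
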