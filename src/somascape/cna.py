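"""Copy-number features and homologous-recombination-deficiency scores.

Per-sample features from allele-specific segment profiles:

* ploidy — length-weighted mean total copy number;
* CNA categories — homozygous deletion (CN 0), loss (CN 1),
  gain/amplification (CN >= 6), neutral range otherwise;
* ploidy-corrected gene amplification — CN >= 6 when ploidy < 2.7,
  CN >= 9 when ploidy >= 2.7;
* percent of genome altered (total CN != 2 by default);
* sub-clonal CNA percent — length of segments with sub-clonal q below
  the FDR cut, over chromosome and genome lengths;
* HRD genomic-scar components: LOH (interstitial minor-allele loss
  > 15 Mb), tAI (telomeric allelic imbalance > 11 Mb not crossing the
  centromere) and LST (large-scale state transitions between >= 10 Mb
  segments after 3 Mb smoothing); HRD-sum is their unweighted sum and a
  sample is HRD when HRD-sum > 42 and the externally supplied HRDetect
  probability is > 0.7.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CnSegment, GenomeModel, HrdScores

logger = logging.getLogger(__name__)

__all__ = [
    "compute_ploidy",
    "categorize_cna",
    "gene_amplified",
    "percent_genome_altered",
    "subclonal_cna_percent",
    "hrd_components",
    "classify_hrd",
]

LOH_MIN_LENGTH = 15_000_000
TAI_MIN_LENGTH = 11_000_000
LST_MIN_SEGMENT = 10_000_000
LST_SMOOTH = 3_000_000


def _covered(segments: Sequence[CnSegment]) -> int:
    return sum(s.length for s in segments)


def compute_ploidy(segments: Sequence[CnSegment], genome: GenomeModel) -> float:
    """Length-weighted mean total copy number over covered bases."""
    if not segments:
        raise ValueError("empty segment profile")
    covered = _covered(segments)
    if covered < 0.9 * genome.total_length:
        logger.warning(
            "segments cover %.1f%% of the genome (<90%%)", 100 * covered / genome.total_length
        )
    return sum(s.total_cn * s.length for s in segments) / covered


def categorize_cna(total_cn: int) -> str:
    """CNA category of an integer copy number."""
    if total_cn < 0:
        raise ValueError("negative copy number")
    if total_cn == 0:
        return "homozygous-deletion"
    if total_cn == 1:
        return "loss"
    if total_cn >= 6:
        return "gain/amplification"
    return "neutral-range"


def gene_amplified(gene_cn: int, ploidy: float) -> bool:
    """Ploidy-corrected amplification call for a gene copy number."""
    if gene_cn < 0 or ploidy <= 0:
        raise ValueError("gene_cn must be >= 0 and ploidy > 0")
    if ploidy < 2.7:
        return gene_cn >= 6
    return gene_cn >= 9


def percent_genome_altered(
    segments: Sequence[CnSegment], genome: GenomeModel, baseline: int = 2
) -> float:
    """Percent of covered bases with total CN different from the baseline."""
    if not segments:
        raise ValueError("empty segment profile")
    covered = _covered(segments)
    altered = sum(s.length for s in segments if s.total_cn != baseline)
    return 100.0 * altered / covered


def subclonal_cna_percent(
    segments: Sequence[CnSegment],
    genome: GenomeModel,
    fdr_cut: float = 0.05,
) -> tuple[pd.Series, float]:
    """Sub-clonal CNA percentage per chromosome and genome-wide.

    Only segments with ``subclonal_q < fdr_cut`` count. The chromosome
    percent divides summed segment lengths by the chromosome length;
    the genome percent divides the overall sum by the genome length.
    """
    per_chrom = pd.Series(0.0, index=list(genome.names))
    total = 0
    for s in segments:
        if s.length > genome.length(s.chrom):
            raise ValueError(f"segment longer than {s.chrom}")
        if s.subclonal_q is not None and s.subclonal_q < fdr_cut:
            per_chrom[s.chrom] += s.length
            total += s.length
    for chrom in per_chrom.index:
        per_chrom[chrom] = 100.0 * per_chrom[chrom] / genome.length(chrom)
    return per_chrom, 100.0 * total / genome.total_length


def _smooth_segments(
    segs: list[CnSegment], min_len: int = LST_SMOOTH
) -> list[CnSegment]:
    """Drop segments shorter than ``min_len`` and merge equal-state neighbours."""
    kept = [s for s in segs if s.length >= min_len]
    out: list[CnSegment] = []
    for s in kept:
        if out and (out[-1].total_cn, out[-1].minor_cn) == (s.total_cn, s.minor_cn):
            prev = out.pop()
            out.append(
                CnSegment(s.sample_id, s.chrom, prev.start, s.end,
                          s.total_cn, s.minor_cn)
            )
        else:
            out.append(s)
    return out


def hrd_components(
    segments: Sequence[CnSegment], genome: GenomeModel,
    hrdetect_prob: Optional[float] = None,
) -> HrdScores:
    """LOH / tAI / LST counts for one sample.

    * LOH: segments with minor_cn = 0, length > 15 Mb, not spanning the
      whole chromosome.
    * tAI: allelic-imbalance segments (minor != major) that reach a
      telomere (either chromosome end), do not cross the centromere and
      exceed 11 Mb.
    * LST: breakpoints between adjacent segments in different copy
      states where both flanking segments are >= 10 Mb, counted after
      smoothing out segments < 3 Mb.
    """
    if not segments:
        raise ValueError("empty segment profile")
    sample_ids = {s.sample_id for s in segments}
    sample_id = sample_ids.pop() if len(sample_ids) == 1 else "NA"
    loh = tai = lst = 0
    for chrom in {s.chrom for s in segments}:
        length = genome.length(chrom)
        cen = genome.centromere(chrom)
        segs = sorted((s for s in segments if s.chrom == chrom), key=lambda s: s.start)
        for s in segs:
            if s.minor_cn == 0 and s.total_cn > 0 and s.length > LOH_MIN_LENGTH:
                if not (s.start == 0 and s.end == length):
                    loh += 1
            if (
                s.minor_cn != s.major_cn
                and s.length > TAI_MIN_LENGTH
                and (s.start == 0 or s.end == length)
                and not (s.start < cen < s.end)
            ):
                tai += 1
        smoothed = _smooth_segments(segs)
        for a, b in zip(smoothed, smoothed[1:]):
            if (a.total_cn, a.minor_cn) != (b.total_cn, b.minor_cn):
                if a.length >= LST_MIN_SEGMENT and b.length >= LST_MIN_SEGMENT:
                    lst += 1
    return HrdScores(sample_id, loh, tai, lst, hrdetect_prob)


def classify_hrd(scores: HrdScores) -> str:
    """HRD call: HRD-sum > 42 AND HRDetect probability > 0.7.

    Returns ``"HRD"``, ``"not-HRD"`` or ``"indeterminate"`` (HRD-sum
    above threshold but no HRDetect probability supplied).
    """
    if scores.hrd_sum > 42:
        if scores.hrdetect_prob is None:
            return "indeterminate"
        return "HRD" if scores.hrdetect_prob > 0.7 else "not-HRD"
    return "not-HRD"
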