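"""Kataegis-SV co-localization ranking.

The genome is divided into fixed 1 Mb bins. APOBEC kataegis loci and SV
breakends are pooled across the cohort into per-bin counts; a bin is
co-localized when both its kataegis count and its breakend count
strictly exceed the genome-wide per-bin mean of the respective event
type. Per chromosome, the co-localized frequency is the percentage of
its bins flagged; a chromosome is enriched when that frequency strictly
exceeds the genome-wide mean frequency (the mean over chromosomes of
the per-chromosome percentages). Chromosomes are finally ranked by the
combined percent: (a) the fraction of cohort samples with at least one
APOBEC locus on the chromosome times (b) the co-localized frequency,
expressed as a percentage.

A z-score variant of the bin flagging rule (count > mean + z_k * sd) is
available behind ``z_threshold``; kataegis frequency (a) can instead be
computed as the chromosome's share of all loci via ``freq_mode``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import GenomeModel, KataegisLocus, SvRecord

__all__ = [
    "bin_counts",
    "flag_colocalized_bins",
    "chromosome_enrichment",
    "kataegis_sample_frequency",
    "combined_percent_ranking",
    "colocalization_table",
]

BIN_DEFAULT = 1_000_000


def bin_counts(
    loci: Sequence[KataegisLocus],
    svs: Sequence[SvRecord],
    genome: GenomeModel,
    bin_size: int = BIN_DEFAULT,
) -> pd.DataFrame:
    """Pool cohort kataegis loci and SV breakends into fixed bins.

    A locus increments every bin it overlaps; each SV contributes both
    of its breakends.
    """
    rows = []
    for chrom, length, _ in genome.chromosomes:
        n_bins = -(-length // bin_size)
        for b in range(n_bins):
            rows.append((chrom, b * bin_size))
    grid = pd.DataFrame(rows, columns=["chrom", "start"])
    grid["kataegis"] = 0
    grid["breakends"] = 0
    index = {(c, s): i for i, (c, s) in enumerate(zip(grid["chrom"], grid["start"]))}

    for locus in loci:
        length = genome.length(locus.chrom)
        if not 1 <= locus.start <= length or not 1 <= locus.end <= length:
            raise ValueError(f"locus outside genome: {locus.chrom}:{locus.start}-{locus.end}")
        first = (locus.start - 1) // bin_size
        last = (locus.end - 1) // bin_size
        for b in range(first, last + 1):
            grid.loc[index[(locus.chrom, b * bin_size)], "kataegis"] += 1
    for sv in svs:
        for chrom, pos in ((sv.chrom1, sv.pos1), (sv.chrom2, sv.pos2)):
            if not 1 <= pos <= genome.length(chrom):
                raise ValueError(f"breakend outside genome: {chrom}:{pos}")
            b = (pos - 1) // bin_size
            grid.loc[index[(chrom, b * bin_size)], "breakends"] += 1
    return grid


def flag_colocalized_bins(
    grid: pd.DataFrame, z_threshold: Optional[float] = None
) -> tuple[pd.DataFrame, float]:
    """Flag bins high in both event types; return grid + mean frequency.

    Default rule: a bin is co-localized iff its kataegis count and its
    breakend count are each strictly greater than the genome-wide
    per-bin mean of that event type. With ``z_threshold`` the cut is
    mean + z * sd instead. The genome-wide mean frequency is the mean
    over chromosomes of the per-chromosome percentage of flagged bins.
    """
    if grid.empty:
        raise ValueError("empty bin grid")
    kat_cut = grid["kataegis"].mean()
    bp_cut = grid["breakends"].mean()
    if z_threshold is not None:
        kat_cut += z_threshold * grid["kataegis"].std(ddof=0)
        bp_cut += z_threshold * grid["breakends"].std(ddof=0)
    flagged = grid.assign(
        colocalized=(grid["kataegis"] > kat_cut) & (grid["breakends"] > bp_cut)
    )
    per_chrom = flagged.groupby("chrom", sort=False)["colocalized"].mean() * 100.0
    return flagged, float(per_chrom.mean())


def chromosome_enrichment(
    flagged: pd.DataFrame, mean_frequency: float
) -> pd.DataFrame:
    """Per-chromosome co-localized frequency and enriched flag.

    A chromosome is enriched iff its co-localized frequency strictly
    exceeds the cohort's genome-wide mean frequency (recomputed from the
    data, never a fixed constant).
    """
    per_chrom = (
        flagged.groupby("chrom", sort=False)["colocalized"].mean() * 100.0
    ).rename("colocalized_frequency")
    out = per_chrom.reset_index()
    out["enriched"] = out["colocalized_frequency"] > mean_frequency
    return out


def kataegis_sample_frequency(
    loci: Sequence[KataegisLocus],
    samples: Sequence[str],
    genome: GenomeModel,
    mode: str = "sample",
) -> pd.Series:
    """Per-chromosome kataegis frequency, as a percentage.

    ``mode="sample"`` (default): percent of cohort samples with >= 1
    APOBEC locus on the chromosome. ``mode="locus"``: the chromosome's
    share of all APOBEC loci.
    """
    apobec = [l for l in loci if l.kataegis_class == "APOBEC"]
    out = pd.Series(0.0, index=list(genome.names), name="kataegis_frequency")
    if mode == "sample":
        n = max(len(samples), 1)
        for chrom in genome.names:
            hit = {l.sample_id for l in apobec if l.chrom == chrom}
            out[chrom] = 100.0 * len(hit) / n
    elif mode == "locus":
        total = max(len(apobec), 1)
        for chrom in genome.names:
            out[chrom] = 100.0 * sum(l.chrom == chrom for l in apobec) / total
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def combined_percent_ranking(
    kataegis_frequency: pd.Series, colocalized_frequency: pd.Series
) -> pd.DataFrame:
    """Combined percent = (a) x (b) as proportions, ranked high to low.

    Ties share the minimum rank.
    """
    a = kataegis_frequency / 100.0
    b = colocalized_frequency / 100.0
    combined = (a * b * 100.0).rename("combined_percent")
    df = pd.DataFrame(
        {
            "kataegis_frequency": kataegis_frequency,
            "colocalized_frequency": colocalized_frequency,
            "combined_percent": combined,
        }
    )
    df["rank"] = (
        df["combined_percent"].rank(method="min", ascending=False).astype(int)
    )
    return df.sort_values(["rank", "combined_percent"], ascending=[True, False])


def colocalization_table(
    loci: Sequence[KataegisLocus],
    svs: Sequence[SvRecord],
    samples: Sequence[str],
    genome: GenomeModel,
    bin_size: int = BIN_DEFAULT,
    z_threshold: Optional[float] = None,
    freq_mode: str = "sample",
) -> dict:
    """Full co-localization analysis for a cohort.

    Returns a dict with the flagged bin grid, the genome-wide mean
    frequency, and the ranked per-chromosome table.
    """
    apobec = [l for l in loci if l.kataegis_class == "APOBEC"]
    grid = bin_counts(apobec, svs, genome, bin_size=bin_size)
    flagged, mean_freq = flag_colocalized_bins(grid, z_threshold=z_threshold)
    enrich = chromosome_enrichment(flagged, mean_freq).set_index("chrom")
    kat_freq = kataegis_sample_frequency(loci, samples, genome, mode=freq_mode)
    ranking = combined_percent_ranking(
        kat_freq, enrich["colocalized_frequency"]
    )
    ranking["enriched"] = enrich["enriched"]
    return {"bins": flagged, "mean_frequency": mean_freq, "chromosomes": ranking}
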