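"""Synthetic cohort generation with known ground truth.

Every downstream stage of the pipeline (signature refitting, kataegis
detection, co-localization ranking, copy-number features, complex-event
calling, immune subtyping, survival stratification) is exercised on
cohorts produced here, because the patient-level data the pipeline was
designed for sit under controlled access. The generators therefore plant
quantities that the downstream modules must recover: signature exposure
vectors, kataegis cluster coordinates, SV class counts, ploidy and
sub-clonal fraction, immune archetype labels, and cluster-dependent
hazards.

Design notes
------------
* The default desk-scale genome is 22 chromosomes x 100 Mb with
  Dirichlet(5) trinucleotide content per chromosome — mildly non-uniform
  without pathological zeros.
* Planted kataegis clusters use inter-mutation gaps drawn uniformly on
  [1, 2000] bp and at least six mutations, matching the detector's locus
  definition so that sensitivity is well defined.
* Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import (
    SNV_CHANNELS_96,
    SV_CHANNELS_32,
    SV_SIZE_BINS,
    TRINUCLEOTIDES_32,
)
from .types import (
    ClinicalRecord,
    CnSegment,
    ExpressionMatrix,
    GeneSetCollection,
    GenomeModel,
    SignatureSet,
    SnvRecord,
    SvRecord,
)

__all__ = [
    "generate_genome",
    "reference_signatures",
    "simulate_snvs",
    "simulate_svs",
    "simulate_cn_profile",
    "default_immune_gene_sets",
    "simulate_expression",
    "simulate_clinical",
    "CohortTruth",
    "simulate_cohort",
]

#: channels qualifying as APOBEC-type: C>T/C>G at TpCpW (TCA / TCT context)
APOBEC_CHANNELS = ("T[C>T]A", "T[C>T]T", "T[C>G]A", "T[C>G]T")


def _channel_parts(channel: str) -> tuple[str, str]:
    """'A[C>T]G' -> ('C>T', 'ACG')."""
    five, rest = channel.split("[")
    sub, three = rest.split("]")
    return sub, f"{five}{sub[0]}{three}"


def generate_genome(
    n_chrom: int = 22, chrom_length: int = 100_000_000, seed: int = 0
) -> GenomeModel:
    """Generate a toy genome model.

    Chromosome names are ``chr1..chrN``, all of the given length, with a
    centromere placed at a seed-dependent position in the middle 40% of
    the chromosome and per-chromosome trinucleotide proportions drawn
    from a symmetric Dirichlet(5).
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if chrom_length < 10_000_000:
        raise ValueError("chrom_length must be >= 10 Mb")
    rng = np.random.default_rng(seed)
    chroms = []
    for i in range(n_chrom):
        cen = int(chrom_length * rng.uniform(0.3, 0.7))
        chroms.append((f"chr{i + 1}", chrom_length, cen))
    freqs = rng.dirichlet(np.full(32, 5.0), size=n_chrom)
    table = pd.DataFrame(
        freqs, index=[c[0] for c in chroms], columns=list(TRINUCLEOTIDES_32)
    )
    return GenomeModel(tuple(chroms), table)


def reference_signatures(
    n_signatures: int = 4,
    seed: int = 0,
    channels: Sequence[str] = SNV_CHANNELS_96,
    alpha: float = 0.2,
    names: Optional[Sequence[str]] = None,
) -> SignatureSet:
    """Draw a synthetic reference signature catalogue.

    Profiles are sparse Dirichlet(alpha) draws over the channel set;
    small alpha yields near-orthogonal, well-identifiable signatures.
    Stands in for an external catalogue (e.g. COSMIC), which is supplied
    as a TSV in real use.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(len(channels), alpha), size=n_signatures)
    if names is None:
        names = [f"Signature_{i + 1}" for i in range(n_signatures)]
    return SignatureSet(
        pd.DataFrame(profiles, index=list(names), columns=list(channels)),
        provenance="reference",
    )


def simulate_snvs(
    genome: GenomeModel,
    signatures: SignatureSet,
    exposures: Sequence[float],
    n_mut: int,
    kataegis_plan: Sequence[tuple] = (),
    seed: int = 0,
    sample_id: str = "S1",
) -> list[SnvRecord]:
    """Simulate a per-sample SNV catalogue.

    Background mutations are drawn i.i.d. from the exposure-weighted
    mixture of the signatures' 96-channel distributions, with positions
    uniform over the genome. Each entry of ``kataegis_plan`` is
    ``(chrom, centre_bp, n, apobec)`` and plants a cluster of ``n``
    mutations with successive gaps uniform on [1, 2000] bp; APOBEC
    clusters use only the TpCpW C>T/C>G channels, others use the
    background mixture.
    """
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape != (signatures.k,):
        raise ValueError("exposure length must match signature count")
    if n_mut and (exposures.min() < -1e-12 or abs(exposures.sum() - 1.0) > 1e-9):
        raise ValueError("exposures must lie on the simplex")
    if n_mut < 0:
        raise ValueError("n_mut must be >= 0")
    rng = np.random.default_rng(seed)
    mixture = exposures @ signatures.profiles.to_numpy(dtype=float)
    channels = list(signatures.channels)
    records: list[SnvRecord] = []

    if n_mut:
        lengths = np.array([c[1] for c in genome.chromosomes], dtype=float)
        chrom_idx = rng.choice(len(lengths), size=n_mut, p=lengths / lengths.sum())
        positions = (rng.random(n_mut) * lengths[chrom_idx]).astype(np.int64) + 1
        ch_idx = rng.choice(len(channels), size=n_mut, p=mixture / mixture.sum())
        names = genome.names
        for ci, pos, ki in zip(chrom_idx, positions, ch_idx):
            sub, ctx = _channel_parts(channels[ki])
            records.append(
                SnvRecord(sample_id, names[ci], int(pos), ctx[1], sub[2], ctx, sub)
            )

    for chrom, centre, n, apobec in kataegis_plan:
        gaps = rng.integers(1, 2001, size=max(n - 1, 0))
        span = int(gaps.sum())
        start = max(1, int(centre) - span // 2)
        pos = start
        positions = [pos]
        for g in gaps:
            pos += int(g)
            positions.append(pos)
        if apobec:
            cluster_channels = rng.choice(APOBEC_CHANNELS, size=n)
        else:
            cluster_channels = rng.choice(
                channels, size=n, p=mixture / mixture.sum()
            )
        for p, ch in zip(positions, cluster_channels):
            sub, ctx = _channel_parts(str(ch))
            records.append(SnvRecord(sample_id, chrom, p, ctx[1], sub[2], ctx, sub))

    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def _draw_size(rng: np.random.Generator, bin_name: str) -> int:
    for name, low, high in SV_SIZE_BINS:
        if name == bin_name:
            hi = high if high is not None else 50_000_000
            return int(np.exp(rng.uniform(np.log(low), np.log(hi))))
    raise ValueError(bin_name)


def simulate_svs(
    genome: GenomeModel,
    class_weights: Sequence[float],
    n_sv: int,
    clustered_region: Optional[tuple] = None,
    seed: int = 0,
    sample_id: str = "S1",
) -> list[SvRecord]:
    """Simulate a per-sample SV set from 32-class weights.

    Sizes are drawn log-uniformly within each class's size bin (the open
    top bin is capped at 50 Mb). If ``clustered_region`` is given as
    ``(chrom, start, end)``, every first breakend is placed inside the
    intersection of the region with the 1 Mb bin containing its start,
    so that the set plants >= min(n_sv, ...) breakpoints in one bin.
    """
    weights = np.asarray(class_weights, dtype=float)
    if weights.shape != (32,):
        raise ValueError("class_weights must have 32 entries")
    if n_sv and (weights.min() < -1e-12 or abs(weights.sum() - 1.0) > 1e-9):
        raise ValueError("class_weights must lie on the simplex")
    rng = np.random.default_rng(seed)
    names = genome.names
    lengths = np.array([c[1] for c in genome.chromosomes], dtype=float)
    out: list[SvRecord] = []
    if clustered_region is not None:
        c_chrom, c_start, c_end = clustered_region
        bin_end = (c_start // 1_000_000 + 1) * 1_000_000
        win_lo, win_hi = c_start, min(c_end, bin_end)
        if win_hi <= win_lo:
            win_hi = min(c_end, win_lo + 1_000_000)
    for i in range(n_sv):
        ki = int(rng.choice(32, p=weights / weights.sum()))
        label = SV_CHANNELS_32[ki]
        svt = label.split("/")[0].upper()
        if svt == "TRA":
            if clustered_region is not None:
                chrom1 = c_chrom
                pos1 = int(rng.integers(win_lo + 1, win_hi + 1))
            else:
                c1 = int(rng.choice(len(names), p=lengths / lengths.sum()))
                chrom1 = names[c1]
                pos1 = int(rng.integers(1, genome.length(chrom1)))
            others = [n for n in names if n != chrom1]
            if not others:
                raise ValueError("cannot place a translocation on a 1-chromosome genome")
            chrom2 = str(rng.choice(others))
            pos2 = int(rng.integers(1, genome.length(chrom2)))
            out.append(SvRecord(sample_id, chrom1, pos1, chrom2, pos2, "TRA"))
        else:
            size = _draw_size(rng, label.split("/")[1])
            if clustered_region is not None:
                chrom = c_chrom
                pos1 = int(rng.integers(win_lo + 1, win_hi + 1))
                pos2 = min(pos1 + size, genome.length(chrom))
                if pos2 <= pos1:
                    pos2 = pos1 + 1
            else:
                ci = int(rng.choice(len(names), p=lengths / lengths.sum()))
                chrom = names[ci]
                cl = genome.length(chrom)
                size = min(size, cl - 2)
                pos1 = int(rng.integers(1, cl - size))
                pos2 = pos1 + size
            out.append(SvRecord(sample_id, chrom, pos1, chrom, pos2, svt))
    return out


def simulate_chromothripsis_svs(
    genome: GenomeModel,
    chrom: str,
    n_sv: int = 35,
    centre: Optional[int] = None,
    mean_gap: int = 50_000,
    seed: int = 0,
    sample_id: str = "S1",
) -> list[SvRecord]:
    """Plant a chromothripsis-like cluster of interleaved SVs.

    Breakpoints are laid down with exponential gaps (mean ``mean_gap``)
    from ``centre``; SV *i* joins breakpoints *i* and *i + 2*, so every
    consecutive pair of intervals overlaps without nesting and the whole
    set forms one interleaved chain. Join types are deliberately skewed
    (60% DEL / 20% DUP / 20% INV) so the cluster also deviates from the
    balanced fragment-join expectation.
    """
    rng = np.random.default_rng(seed)
    length = genome.length(chrom)
    if centre is None:
        centre = length // 2
    gaps = rng.exponential(mean_gap, size=n_sv + 2)
    pos = (centre + np.cumsum(gaps)).astype(np.int64)
    pos = np.clip(pos, 1, length)
    types = rng.choice(["DEL", "DUP", "INV"], size=n_sv, p=[0.6, 0.2, 0.2])
    out = []
    for i in range(n_sv):
        a, b = int(pos[i]), int(pos[i + 2])
        if b <= a:
            b = a + 1
        out.append(SvRecord(sample_id, chrom, a, chrom, b, str(types[i])))
    return out


def simulate_cn_profile(
    genome: GenomeModel,
    target_ploidy: float = 2.0,
    subclonal_pct: float = 0.0,
    complex_chrom: Optional[str] = None,
    seed: int = 0,
    sample_id: str = "S1",
    segments_per_chrom: int = 20,
) -> list[CnSegment]:
    """Simulate a clonal + sub-clonal segment profile.

    The genome is partitioned into ``segments_per_chrom`` equal segments
    per chromosome. Total copy numbers mix floor/ceil of the target so
    the length-weighted mean ploidy matches ``target_ploidy`` to within
    one segment's weight; a random subset of segments covering
    approximately ``subclonal_pct`` percent of the genome is flagged
    sub-clonal (q drawn < 0.05). If ``complex_chrom`` is set, that
    chromosome is rebuilt as >= 7 oscillations between two copy states.
    """
    if not 0 <= subclonal_pct <= 100:
        raise ValueError("subclonal_pct must lie in [0, 100]")
    if target_ploidy <= 0:
        raise ValueError("target_ploidy must be positive")
    rng = np.random.default_rng(seed)
    lo = int(np.floor(target_ploidy))
    hi = lo + 1
    frac_hi = target_ploidy - lo

    segs: list[CnSegment] = []
    plain: list[int] = []  # indices eligible for sub-clonal flagging
    for name, length, _ in genome.chromosomes:
        if name == complex_chrom:
            # oscillating profile: 16 alternating segments between two states
            n_osc = 16
            bounds = np.linspace(0, length, n_osc + 1, dtype=np.int64)
            states = [max(lo, 1), max(lo, 1) + 1]
            for j in range(n_osc):
                cn = states[j % 2]
                segs.append(
                    CnSegment(sample_id, name, int(bounds[j]), int(bounds[j + 1]), cn, cn // 2)
                )
            continue
        bounds = np.linspace(0, length, segments_per_chrom + 1, dtype=np.int64)
        for j in range(segments_per_chrom):
            cn = hi if rng.random() < frac_hi else lo
            plain.append(len(segs))
            segs.append(
                CnSegment(sample_id, name, int(bounds[j]), int(bounds[j + 1]), cn, cn // 2)
            )

    # correct the floor/ceil mix toward the exact target ploidy
    total_len = sum(s.length for s in segs)
    def ploidy_of(ss):
        return sum(s.total_cn * s.length for s in ss) / total_len

    order = rng.permutation(plain)
    for idx in order:
        cur = ploidy_of(segs)
        if abs(cur - target_ploidy) < 0.02:
            break
        s = segs[idx]
        if cur < target_ploidy and s.total_cn == lo:
            segs[idx] = CnSegment(sample_id, s.chrom, s.start, s.end, hi, hi // 2)
        elif cur > target_ploidy and s.total_cn == hi:
            segs[idx] = CnSegment(sample_id, s.chrom, s.start, s.end, lo, lo // 2)

    # flag sub-clonal segments up to the target percentage
    target_bases = subclonal_pct / 100.0 * total_len
    acc = 0
    for idx in rng.permutation(plain):
        if acc >= target_bases:
            break
        s = segs[idx]
        if acc + s.length > target_bases + 0.02 * total_len:
            continue
        q = float(rng.uniform(0.0, 0.049))
        segs[idx] = CnSegment(sample_id, s.chrom, s.start, s.end, s.total_cn, s.minor_cn, q)
        acc += s.length

    segs.sort(key=lambda s: (s.chrom, s.start))
    return segs


# 18 cell types mirroring consensus TME deconvolution outputs
LYMPHOID_CELL_TYPES = (
    "T_cells_CD4",
    "T_cells_CD8",
    "T_regulatory_cells",
    "T_cells_gamma_delta",
    "B_cells",
    "Plasma_cells",
    "NK_cells",
    "Cytotoxic_cells",
    "Immune_Score",
    "Lymphocytes_aggregate",
)
MYELOID_CELL_TYPES = (
    "Macrophages",
    "Macrophages_M1",
    "Macrophages_M2",
    "Monocytes",
    "Neutrophils",
    "Dendritic_cells",
    "Eosinophils",
    "Mast_cells",
)
CELL_TYPES_18 = LYMPHOID_CELL_TYPES + MYELOID_CELL_TYPES


def default_immune_gene_sets(
    n_genes: int = 2000, genes_per_set: int = 30, seed: int = 0
) -> tuple[GeneSetCollection, list, list]:
    """Synthetic marker gene sets for the 18 default immune cell types.

    Genes are named ``G0001..G{n_genes}``; each cell type receives a
    disjoint marker set. Returns the collection plus the lymphoid and
    myeloid cell-type name lists used by the cluster labeller.
    """
    if genes_per_set * len(CELL_TYPES_18) > n_genes:
        raise ValueError("gene universe too small for disjoint marker sets")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    chosen = rng.choice(n_genes, size=genes_per_set * len(CELL_TYPES_18), replace=False)
    sets = {}
    for i, ct in enumerate(CELL_TYPES_18):
        idx = chosen[i * genes_per_set : (i + 1) * genes_per_set]
        sets[ct] = tuple(genes[j] for j in sorted(idx))
    coll = GeneSetCollection(sets, {ct: "synthetic marker set" for ct in CELL_TYPES_18})
    return coll, list(LYMPHOID_CELL_TYPES), list(MYELOID_CELL_TYPES)


def simulate_expression(
    n_genes: int,
    samples_per_cluster: Sequence[int],
    gene_sets: GeneSetCollection,
    separation: float = 3.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    lymphoid_sets: Sequence[str] = LYMPHOID_CELL_TYPES,
    myeloid_sets: Sequence[str] = MYELOID_CELL_TYPES,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Simulate a TPM-like matrix with four planted immune archetypes.

    Archetype 1 (immune hot) up-shifts lymphoid and myeloid marker genes
    by ``separation`` in log space; archetype 2 (suppressed) up-shifts
    myeloid markers only; archetype 3 (moderate) lymphoid markers at
    half effect; archetype 4 (cold) has no shift. Noise is log-normal
    with log-scale standard deviation ``noise_sd``.
    """
    if len(samples_per_cluster) != 4:
        raise ValueError("samples_per_cluster must have 4 entries")
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    missing = gene_sets.all_genes() - set(genes)
    if missing:
        raise ValueError(f"gene sets reference absent genes: {sorted(missing)[:5]} ...")
    rng = np.random.default_rng(seed)

    lym_idx = sorted(
        {gene_index[g] for s in lymphoid_sets for g in gene_sets[s] if s in gene_sets.sets}
    )
    mye_idx = sorted(
        {gene_index[g] for s in myeloid_sets for g in gene_sets[s] if s in gene_sets.sets}
    )

    n_samples = int(sum(samples_per_cluster))
    labels = np.repeat(np.arange(1, 5), samples_per_cluster)
    base = rng.normal(3.0, 1.0, size=n_genes)  # per-gene baseline log expression
    log_expr = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    shifts = {
        1: [(lym_idx, separation), (mye_idx, separation)],
        2: [(mye_idx, separation)],
        3: [(lym_idx, separation / 2.0)],
        4: [],
    }
    for cl, spec_list in shifts.items():
        cols = np.flatnonzero(labels == cl)
        for idx, eff in spec_list:
            log_expr[np.ix_(idx, cols)] += eff
    values = pd.DataFrame(
        np.exp(log_expr), index=genes,
        columns=[f"S{i + 1:03d}" for i in range(n_samples)],
    )
    return ExpressionMatrix(values, scale="TPM"), labels


def simulate_clinical(
    labels: Sequence[int],
    hazard_by_cluster: Sequence[float],
    censor_rate: float = 0.01,
    max_follow_up: float = 120.0,
    seed: int = 0,
    sample_ids: Optional[Sequence[str]] = None,
    stage_probs: Sequence[float] = (0.1, 0.35, 0.45, 0.1),
    treatment_levels: Sequence[str] = ("CF", "DCF", "DCF+RT"),
    treatment_probs: Sequence[float] = (0.3, 0.35, 0.35),
) -> list[ClinicalRecord]:
    """Simulate survival and covariates with cluster-dependent hazards.

    Event times are exponential with the cluster's hazard (per month);
    censoring is an independent exponential with rate ``censor_rate``
    truncated at ``max_follow_up`` months. PFS is generated as a scaled
    copy of the OS latent time with its own censoring draw.
    """
    hazards = np.asarray(hazard_by_cluster, dtype=float)
    if (hazards <= 0).any():
        raise ValueError("hazards must be positive")
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > len(hazards):
        raise ValueError("label outside hazard table")
    rng = np.random.default_rng(seed)
    n = len(labels)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    event_t = rng.exponential(1.0 / hazards[labels - 1])
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_t = np.full(n, np.inf)
    censor_t = np.minimum(censor_t, max_follow_up)
    os_t = np.minimum(event_t, censor_t)
    os_e = (event_t <= censor_t).astype(int)
    pfs_latent = event_t * rng.uniform(0.5, 1.0, size=n)
    pfs_t = np.minimum(pfs_latent, censor_t)
    pfs_e = (pfs_latent <= censor_t).astype(int)
    stages = rng.choice(["I", "II", "III", "IV"], size=n, p=stage_probs)
    treatments = rng.choice(list(treatment_levels), size=n, p=treatment_probs)
    pet = rng.choice(["responder", "non-responder"], size=n)
    return [
        ClinicalRecord(
            sample_ids[i],
            float(os_t[i]),
            int(os_e[i]),
            float(pfs_t[i]),
            int(pfs_e[i]),
            str(stages[i]),
            str(treatments[i]),
            str(pet[i]),
        )
        for i in range(n)
    ]


@dataclass
class CohortTruth:
    """Ground truth planted by :func:`simulate_cohort`."""

    sample_ids: list
    exposures: dict  # sample -> list of exposure proportions
    signature_names: list
    kataegis_loci: dict  # sample -> list of (chrom, start, end, class)
    sv_class_weights: dict  # sample -> 32-list
    ploidy: dict
    subclonal_pct: dict
    complex_chrom: dict  # sample -> chrom name or None
    immune_cluster: dict  # sample -> 1..4
    hazard: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def simulate_cohort(
    n_samples: int = 60,
    seed: int = 0,
    n_chrom: int = 22,
    chrom_length: int = 100_000_000,
    n_signatures: int = 4,
    n_mut_per_sample: int = 3000,
    n_sv_per_sample: int = 120,
    kataegis_rate: float = 2.0,
    hotspot_chrom: str = "chr8",
    separation: float = 3.0,
    noise_sd: float = 0.5,
    hazard_by_cluster: Sequence[float] = (0.01, 0.05, 0.02, 0.03),
):
    """Generate a full synthetic cohort and its ground truth.

    Returns a dict with the genome, reference signatures, per-sample SNV /
    SV / CN data, expression matrix, gene sets, clinical records and a
    :class:`CohortTruth`. Kataegis loci are planted Poisson(kataegis_rate)
    per sample, biased toward ``hotspot_chrom`` where SV breakpoints are
    also concentrated, giving the co-localization module a recoverable
    hotspot.
    """
    rng = np.random.default_rng(seed)
    genome = generate_genome(n_chrom, chrom_length, seed=int(rng.integers(2**31)))
    sigs = reference_signatures(n_signatures, seed=int(rng.integers(2**31)))
    gene_sets, lymphoid, myeloid = default_immune_gene_sets(seed=int(rng.integers(2**31)))

    per4 = n_samples // 4
    samples_per_cluster = [per4, per4, per4, n_samples - 3 * per4]
    expr, labels = simulate_expression(
        2000, samples_per_cluster, gene_sets, separation, noise_sd,
        seed=int(rng.integers(2**31)),
    )
    sample_ids = list(expr.samples)
    clinical = simulate_clinical(
        labels, hazard_by_cluster, seed=int(rng.integers(2**31)), sample_ids=sample_ids
    )

    snvs: dict = {}
    svs: dict = {}
    segments: dict = {}
    truth = CohortTruth(
        sample_ids, {}, sigs.names, {}, {}, {}, {}, {}, {}, {}
    )
    names = genome.names
    for i, sid in enumerate(sample_ids):
        expo = rng.dirichlet(np.full(n_signatures, 1.0))
        n_kat = int(rng.poisson(kataegis_rate))
        plan = []
        for _ in range(n_kat):
            chrom = hotspot_chrom if rng.random() < 0.5 else str(rng.choice(names))
            centre = int(rng.integers(1_000_000, genome.length(chrom) - 1_000_000))
            n = int(rng.integers(6, 15))
            plan.append((chrom, centre, n, True))
        s = simulate_snvs(
            genome, sigs, expo, n_mut_per_sample, plan,
            seed=int(rng.integers(2**31)), sample_id=sid,
        )
        weights = rng.dirichlet(np.full(32, 1.0))
        sv = simulate_svs(
            genome, weights, n_sv_per_sample, None,
            seed=int(rng.integers(2**31)), sample_id=sid,
        )
        # concentrate extra breakpoints on the hotspot chromosome
        hot = simulate_svs(
            genome, weights, 15,
            (hotspot_chrom, 4_000_000, 5_000_000),
            seed=int(rng.integers(2**31)), sample_id=sid,
        )
        sv = sv + hot
        ploidy = float(rng.uniform(1.8, 4.2))
        sub_pct = float(rng.uniform(5, 40))
        complex_chrom = "chr18" if rng.random() < 0.3 else None
        if complex_chrom is not None:
            sv += simulate_chromothripsis_svs(
                genome, complex_chrom, n_sv=35,
                seed=int(rng.integers(2**31)), sample_id=sid,
            )
        seg = simulate_cn_profile(
            genome, ploidy, sub_pct, complex_chrom,
            seed=int(rng.integers(2**31)), sample_id=sid,
        )
        snvs[sid] = s
        svs[sid] = sv
        segments[sid] = seg
        truth.exposures[sid] = [float(x) for x in expo]
        truth.kataegis_loci[sid] = [
            (c, int(p), int(p), "APOBEC" if a else "non-APOBEC") for c, p, n, a in plan
        ]
        truth.sv_class_weights[sid] = [float(x) for x in weights]
        truth.ploidy[sid] = ploidy
        truth.subclonal_pct[sid] = sub_pct
        truth.complex_chrom[sid] = complex_chrom
        truth.immune_cluster[sid] = int(labels[i])
        truth.hazard[sid] = float(hazard_by_cluster[labels[i] - 1])

    return {
        "genome": genome,
        "signatures": sigs,
        "gene_sets": gene_sets,
        "lymphoid": lymphoid,
        "myeloid": myeloid,
        "snvs": snvs,
        "svs": svs,
        "segments": segments,
        "expression": expr,
        "clinical": clinical,
        "truth": truth,
    }
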