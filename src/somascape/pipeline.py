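"""End-to-end orchestration on a synthetic cohort.

``run_all`` generates the default cohort, runs every analysis stage,
writes tabular results, and reports recovery checks against the planted
ground truth (exposure MAE, kataegis sensitivity, ploidy and sub-clonal
recovery, hotspot rank, immune ARI, survival separation).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import io
from .cna import compute_ploidy, hrd_components, percent_genome_altered, subclonal_cna_percent
from .colocalization import colocalization_table
from .complex_events import call_complex_events
from .config import PipelineConfig
from .immune import consensus_kmeans, enrichment_scores, label_clusters
from .kataegis import detect_kataegis
from .signatures import build_snv_catalogue, prune_and_reassign, refit_exposure_matrix
from .simulate import simulate_cohort
from .survival import logrank_test
from .sv_signatures import build_sv_catalogue, flag_clustered_breakpoints

logger = logging.getLogger(__name__)

__all__ = ["run_all"]


def run_all(
    outdir,
    n_samples: int = 60,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full pipeline on the default synthetic cohort.

    Writes result tables under ``outdir`` and returns the recovery
    report as a dict (also written as ``recovery.json``).
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(n_samples=n_samples, seed=seed)
    genome = cohort["genome"]
    truth = cohort["truth"]
    samples = truth.sample_ids

    # --- substitution signatures -------------------------------------
    records = [r for sid in samples for r in cohort["snvs"][sid]]
    catalogue = build_snv_catalogue(records, samples)
    io.write_catalogue(catalogue, outdir / "snv_catalogue.tsv")
    exposures = refit_exposure_matrix(catalogue, cohort["signatures"])
    pruned = prune_and_reassign(
        exposures, catalogue, cohort["signatures"], cfg.prune_threshold
    )
    pruned.to_csv(outdir / "snv_exposures.tsv", sep="\t")
    true_expo = pd.DataFrame(truth.exposures).T.loc[samples]
    true_expo.columns = exposures.columns
    exposure_mae = float((exposures - true_expo).abs().to_numpy().mean())

    # --- SV catalogue ------------------------------------------------
    all_svs = []
    for sid in samples:
        all_svs.extend(
            flag_clustered_breakpoints(
                cohort["svs"][sid], cfg.sv_cluster_bin, cfg.sv_cluster_min_bp
            )
        )
    sv_catalogue = build_sv_catalogue(all_svs, samples)
    io.write_catalogue(sv_catalogue, outdir / "sv_catalogue.tsv")

    # --- kataegis ----------------------------------------------------
    loci = detect_kataegis(
        cohort["snvs"], genome,
        window=cfg.kat_window, step=cfg.kat_step, min_mut=cfg.kat_min_mut,
        max_imd=cfg.kat_max_imd, q_cut=cfg.kat_q_cut,
        apobec_cutoff=cfg.apobec_cutoff,
    )
    pd.DataFrame(
        [(l.sample_id, l.chrom, l.start, l.end, l.n_mut, l.hypermutation_score,
          l.apobec_score, l.q_value, l.kataegis_class) for l in loci],
        columns=["sample", "chrom", "start", "end", "n_mut",
                 "hypermutation_score", "apobec_score", "q", "class"],
    ).to_csv(outdir / "kataegis_loci.tsv", sep="\t", index=False)
    n_planted = sum(len(v) for v in truth.kataegis_loci.values())
    recovered = 0
    for sid, planted in truth.kataegis_loci.items():
        sample_loci = [l for l in loci if l.sample_id == sid]
        for chrom, start, end, _cls in planted:
            if any(
                l.chrom == chrom and l.start - 50_000 <= start <= l.end + 50_000
                for l in sample_loci
            ):
                recovered += 1
    kataegis_sensitivity = recovered / n_planted if n_planted else float("nan")

    # --- co-localization ---------------------------------------------
    coloc = colocalization_table(
        loci, all_svs, samples, genome,
        bin_size=cfg.coloc_bin, z_threshold=cfg.coloc_z_threshold,
        freq_mode=cfg.coloc_freq_mode,
    )
    coloc["chromosomes"].to_csv(outdir / "colocalization.tsv", sep="\t")
    hotspot_rank = int(coloc["chromosomes"].loc["chr8", "rank"])

    # --- copy number / HRD -------------------------------------------
    cn_rows = []
    ploidy_err = []
    subclonal_err = []
    for sid in samples:
        segs = cohort["segments"][sid]
        ploidy = compute_ploidy(segs, genome)
        pga = percent_genome_altered(segs, genome, baseline=cfg.pga_baseline)
        _, sub_pct = subclonal_cna_percent(segs, genome, cfg.subclonal_fdr)
        hrd = hrd_components(segs, genome)
        cn_rows.append((sid, ploidy, pga, sub_pct, hrd.loh, hrd.tai, hrd.lst, hrd.hrd_sum))
        ploidy_err.append(abs(ploidy - truth.ploidy[sid]))
        subclonal_err.append(abs(sub_pct - truth.subclonal_pct[sid]))
    pd.DataFrame(
        cn_rows,
        columns=["sample", "ploidy", "pct_genome_altered", "subclonal_pct",
                 "loh", "tai", "lst", "hrd_sum"],
    ).to_csv(outdir / "cna_features.tsv", sep="\t", index=False)

    # --- complex events ----------------------------------------------
    calls, flags = call_complex_events(
        cohort["svs"], cohort["segments"], genome,
        min_interleaved=cfg.ce_min_interleaved,
        min_oscillations=cfg.ce_min_oscillations,
        q_enrichment_cut=cfg.ce_q_enrichment,
        q_exponential_cut=cfg.ce_q_exponential,
        q_joins_cut=cfg.ce_q_joins,
        min_interleaved_b=cfg.ce_min_interleaved_b,
        min_events=cfg.ce_min_events,
        seed=seed,
    )
    pd.DataFrame(
        [(c.sample_id, c.chrom, c.n_interleaved, c.n_oscillations3,
          c.q_enrichment, c.q_exponential, c.q_joins, c.criterion, c.called)
         for c in calls],
        columns=["sample", "chrom", "n_interleaved", "n_oscillations",
                 "q_enrichment", "q_exponential", "q_joins", "criterion", "called"],
    ).to_csv(outdir / "complex_events.tsv", sep="\t", index=False)
    complex_truth = {s: truth.complex_chrom[s] is not None for s in samples}
    tp = sum(flags[s] and complex_truth[s] for s in samples)
    fp = sum(flags[s] and not complex_truth[s] for s in samples)
    n_pos = sum(complex_truth.values())
    complex_sensitivity = tp / n_pos if n_pos else float("nan")
    complex_false_rate = fp / max(len(samples) - n_pos, 1)

    # --- immune subtyping --------------------------------------------
    scores = enrichment_scores(cohort["expression"], cohort["gene_sets"], cfg.ssgsea_alpha)
    scores.to_csv(outdir / "immune_scores.tsv", sep="\t")
    assignment = consensus_kmeans(
        scores, k_range=list(cfg.k_range),
        n_perm=min(cfg.consensus_perms, 200), n_gap_refs=cfg.gap_refs, seed=seed,
    )
    assignment = label_clusters(
        scores, assignment, cohort["lymphoid"], cohort["myeloid"]
    )
    out = assignment.labels.to_frame()
    out["label"] = out["cluster"].map(assignment.cluster_labels)
    out.to_csv(outdir / "immune_clusters.tsv", sep="\t")
    true_labels = np.array([truth.immune_cluster[s] for s in samples])
    ari = float(adjusted_rand_score(true_labels, assignment.labels.loc[samples]))

    # --- survival ----------------------------------------------------
    clinical = cohort["clinical"]
    times = np.array([c.os_months for c in clinical])
    events = np.array([c.os_event for c in clinical])
    lr_truth = logrank_test(times, events, true_labels)
    lr_called = logrank_test(times, events, assignment.labels.loc[samples].to_numpy())
    io.write_clinical(clinical, outdir / "clinical.tsv")

    report = {
        "n_samples": n_samples,
        "seed": seed,
        "exposure_mae": exposure_mae,
        "kataegis_sensitivity": kataegis_sensitivity,
        "n_kataegis_loci": len(loci),
        "coloc_mean_frequency_pct": coloc["mean_frequency"],
        "hotspot_chrom_rank": hotspot_rank,
        "ploidy_mae": float(np.mean(ploidy_err)),
        "subclonal_pct_mae": float(np.mean(subclonal_err)),
        "n_complex_genomes": int(sum(flags.values())),
        "complex_sensitivity": complex_sensitivity,
        "complex_false_rate": complex_false_rate,
        "consensus_k": assignment.k,
        "consensus_stability": assignment.stability,
        "immune_ari": ari,
        "logrank_p_true_clusters": lr_truth.p,
        "logrank_p_called_clusters": lr_called.p,
    }
    with open(outdir / "recovery.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
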