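"""Pipeline configuration: every threshold in one versioned object.

Defaults are the analysis' published operating points; any field can be
overridden from a YAML file via :func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    version: int = CONFIG_VERSION

    # substitution signatures
    snv_k: int = 4
    nmf_restarts: int = 50
    nmf_max_iter: int = 10_000
    nmf_tol: float = 1e-6
    prune_threshold: float = 0.10

    # rearrangement signatures
    sv_k: int = 3
    sv_cluster_bin: int = 1_000_000
    sv_cluster_min_bp: int = 10
    rs_like_cosine: float = 0.80

    # kataegis
    kat_window: int = 10_000
    kat_step: int = 5_000
    kat_min_mut: int = 6
    kat_max_imd: int = 2_000
    kat_q_cut: float = 0.05
    apobec_cutoff: float = 0.5

    # co-localization
    coloc_bin: int = 1_000_000
    coloc_z_threshold: float | None = None  # None = strict mean rule
    coloc_freq_mode: str = "sample"

    # CNA / HRD
    subclonal_fdr: float = 0.05
    pga_baseline: int = 2
    hrd_sum_cut: int = 42
    hrdetect_cut: float = 0.7

    # complex events
    ce_min_interleaved: int = 10
    ce_min_oscillations: int = 6
    ce_q_enrichment: float = 0.05
    ce_q_exponential: float = 0.05
    ce_q_joins: float = 0.2
    ce_min_interleaved_b: int = 30
    ce_min_events: int = 1  # "at least one" complex event per genome

    # immune
    ssgsea_alpha: float = 0.25
    k_range: tuple = (2, 3, 4, 5, 6, 7, 8)
    consensus_perms: int = 1000
    gap_refs: int = 50
    de_logfc_cut: float = 1.5
    de_q_cut: float = 0.05
    gsea_perms: int = 1000

    # survival
    presence_cutoff: float = 0.15


def load_config(path=None) -> PipelineConfig:
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key {key!r}")
        setattr(cfg, key, value)
    return cfg


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
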