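"""Structural-rearrangement signature analysis.

SVs are classified into 32 classes: {deletion, duplication, inversion}
by five size bins (1-10 kb, 10-100 kb, 100 kb-1 Mb, 1-10 Mb, >10 Mb)
and a clustered/non-clustered flag, plus translocations (no size bins)
by the clustered flag. A breakpoint is clustered when it falls in a
fixed 1 Mb genome bin holding at least 10 of the sample's breakpoints.
Catalogue construction, NMF extraction and cosine matching reuse the
substitution-signature machinery on the 32 channels; matches with
cosine below 0.80 are reported with a "-like" suffix. The sub-threshold
exposure pruning applied to substitution signatures is deliberately not
applied here.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import SV_CHANNELS_32, SV_SIZE_BINS
from .types import SignatureSet, SvRecord
from .signatures import extract_signatures_nmf, match_signatures_cosine

logger = logging.getLogger(__name__)

__all__ = [
    "flag_clustered_breakpoints",
    "classify_sv",
    "build_sv_catalogue",
    "extract_and_match_rs",
]

BIN_SIZE_DEFAULT = 1_000_000
MIN_BREAKPOINTS_DEFAULT = 10


def flag_clustered_breakpoints(
    svs: Sequence[SvRecord],
    bin_size: int = BIN_SIZE_DEFAULT,
    min_bp: int = MIN_BREAKPOINTS_DEFAULT,
) -> list[SvRecord]:
    """Set the clustered flag on one sample's SVs.

    Both breakends of every SV are assigned to fixed non-overlapping
    bins of ``bin_size`` bp; an SV is clustered iff either breakend
    falls in a bin holding >= ``min_bp`` breakends of this sample.
    """
    samples = {r.sample_id for r in svs}
    if len(samples) > 1:
        raise ValueError("flag_clustered_breakpoints expects one sample's SVs")
    counts: Counter = Counter()
    for r in svs:
        counts[(r.chrom1, (r.pos1 - 1) // bin_size)] += 1
        counts[(r.chrom2, (r.pos2 - 1) // bin_size)] += 1
    out = []
    for r in svs:
        hit = (
            counts[(r.chrom1, (r.pos1 - 1) // bin_size)] >= min_bp
            or counts[(r.chrom2, (r.pos2 - 1) // bin_size)] >= min_bp
        )
        out.append(r.with_clustered(bool(hit)))
    return out


def classify_sv(record: SvRecord) -> str:
    """Map an SV (clustered flag set) to its 32-class channel label."""
    if record.clustered is None:
        raise ValueError("clustered flag must be set before classification")
    clust = "clustered" if record.clustered else "non-clustered"
    if record.sv_type == "TRA":
        return f"tra/{clust}"
    size = record.size
    if size < SV_SIZE_BINS[0][1]:
        logger.warning(
            "SV size %d bp below 1 kb; clamped into the lowest size bin", size
        )
        size = SV_SIZE_BINS[0][1]
    for name, low, high in SV_SIZE_BINS:
        if size >= low and (high is None or size < high):
            return f"{record.sv_type.lower()}/{name}/{clust}"
    raise AssertionError("unreachable")


def build_sv_catalogue(
    svs: Sequence[SvRecord], samples: Sequence[str]
) -> pd.DataFrame:
    """Count classified SVs into the samples x 32 catalogue."""
    samples = list(samples)
    index = {s: i for i, s in enumerate(samples)}
    channel_index = {c: j for j, c in enumerate(SV_CHANNELS_32)}
    counts = np.zeros((len(samples), 32), dtype=np.int64)
    for r in svs:
        if r.sample_id not in index:
            raise KeyError(f"unknown sample {r.sample_id!r}")
        counts[index[r.sample_id], channel_index[classify_sv(r)]] += 1
    return pd.DataFrame(counts, index=samples, columns=list(SV_CHANNELS_32))


def extract_and_match_rs(
    catalogue: pd.DataFrame,
    reference: Optional[SignatureSet],
    k: int,
    seed: int = 0,
    n_restarts: int = 50,
    like_threshold: float = 0.80,
) -> tuple[SignatureSet, pd.DataFrame, Optional[pd.DataFrame]]:
    """Extract rearrangement signatures and match them to a reference.

    Delegates to the NMF and cosine machinery on 32 channels; exposures
    are per-sample proportions ready for tertile or presence
    stratification. Matches below ``like_threshold`` cosine keep the
    reference name with a "-like" suffix.
    """
    sigs, exposures, _ = extract_signatures_nmf(
        catalogue, k, n_restarts=n_restarts, seed=seed
    )
    match = None
    if reference is not None:
        match = match_signatures_cosine(sigs, reference, like_threshold=like_threshold)
        renames = dict(zip(match["extracted"], match["label"]))
        # keep labels unique if two factors match the same reference signature
        seen: Counter = Counter()
        uniq = {}
        for old, new in renames.items():
            seen[new] += 1
            uniq[old] = new if seen[new] == 1 else f"{new}.{seen[new]}"
        sigs = SignatureSet(
            sigs.profiles.rename(index=uniq), provenance="extracted"
        )
        exposures = exposures.rename(columns=uniq)
    return sigs, exposures, match
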