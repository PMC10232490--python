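"""Core record and container types.

Coordinate conventions
----------------------
* ``SnvRecord.pos`` and ``SvRecord.pos1/pos2`` are 1-based positions as
  in VCF; BEDPE input (0-based starts) is converted at the I/O boundary.
* ``CnSegment`` intervals are 0-based half-open, the natural convention
  for length arithmetic and binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .constants import (
    SNV_CHANNELS_96,
    SUBSTITUTION_CLASSES,
    SV_TYPES,
    TRINUCLEOTIDES_32,
    normalize_substitution,
    snv_channel,
)

__all__ = [
    "SnvRecord",
    "SvRecord",
    "CnSegment",
    "ClinicalRecord",
    "GenomeModel",
    "GeneSetCollection",
    "ExpressionMatrix",
    "SignatureSet",
    "KataegisLocus",
    "HrdScores",
    "ComplexEventCall",
]


@dataclass(frozen=True)
class SnvRecord:
    """A somatic single-nucleotide variant with its trinucleotide context."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    context3: str  # pyrimidine-strand 3-mer, middle base = normalized ref
    subst_class: str  # one of the six pyrimidine-strand classes

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref equals alt")
        if self.subst_class not in SUBSTITUTION_CLASSES:
            raise ValueError(f"bad substitution class {self.subst_class!r}")
        if len(self.context3) != 3 or self.context3[1] != self.subst_class[0]:
            raise ValueError(
                f"context {self.context3!r} inconsistent with class {self.subst_class!r}"
            )
        expected, _ = normalize_substitution(self.ref, self.alt, self._raw_context())
        if expected != self.subst_class:
            raise ValueError(
                f"class {self.subst_class!r} inconsistent with {self.ref}>{self.alt}"
            )

    def _raw_context(self) -> str:
        # context3 is stored pyrimidine-normalized; reconstruct a context on
        # the reported strand for the consistency check.
        from .constants import reverse_complement

        if self.ref in ("C", "T"):
            return self.context3
        return reverse_complement(self.context3)

    @property
    def channel(self) -> str:
        return snv_channel(self.subst_class, self.context3)

    @classmethod
    def from_alleles(
        cls, sample_id: str, chrom: str, pos: int, ref: str, alt: str, context3: str
    ) -> "SnvRecord":
        """Build a record, normalizing purine-strand calls to the pyrimidine strand."""
        subst, ctx = normalize_substitution(ref, alt, context3)
        return cls(sample_id, chrom, pos, ref.upper(), alt.upper(), ctx, subst)


@dataclass
class SvRecord:
    """A somatic structural variant as a breakend pair."""

    sample_id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str  # DEL / DUP / INV / TRA
    size: Optional[int] = None
    clustered: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if (self.sv_type == "TRA") != (self.chrom1 != self.chrom2):
            raise ValueError("TRA if and only if chrom1 != chrom2")
        if self.sv_type != "TRA":
            expected = abs(self.pos2 - self.pos1)
            if self.size is None:
                self.size = expected
            elif self.size != expected:
                raise ValueError("size must equal |pos2 - pos1| for intra-chromosomal SVs")
        elif self.size is not None:
            raise ValueError("translocations carry no size")

    def with_clustered(self, flag: bool) -> "SvRecord":
        return replace(self, clustered=flag)


@dataclass(frozen=True)
class CnSegment:
    """An allele-specific copy-number segment (0-based half-open)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int
    subclonal_q: Optional[float] = None  # FDR q; None means clonal

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.total_cn < 0:
            raise ValueError("negative copy number")
        if self.minor_cn < 0 or self.minor_cn > -(-self.total_cn // 2):
            raise ValueError("minor_cn must lie in [0, ceil(total_cn/2)]")
        if self.subclonal_q is not None and not 0 <= self.subclonal_q <= 1:
            raise ValueError("subclonal_q outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def major_cn(self) -> int:
        return self.total_cn - self.minor_cn


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    os_months: float
    os_event: int
    pfs_months: float
    pfs_event: int
    stage: str  # I / II / III / IV
    treatment: str
    pet_response: str  # responder / non-responder / NA

    def __post_init__(self) -> None:
        if self.os_months < 0 or self.pfs_months < 0:
            raise ValueError("negative survival time")
        if self.os_event not in (0, 1) or self.pfs_event not in (0, 1):
            raise ValueError("event indicators must be 0/1")


@dataclass(frozen=True)
class GenomeModel:
    """A toy genome: chromosome sizes, centromeres and trinucleotide content.

    ``trinucleotide_freq`` is a chromosomes x 32 DataFrame of
    pyrimidine-strand trinucleotide proportions (rows sum to one). It
    stands in for reference-genome context counts and drives both SNV
    simulation and the per-window trinucleotide tests.
    """

    chromosomes: tuple  # of (name, length, centromere)
    trinucleotide_freq: pd.DataFrame

    def __post_init__(self) -> None:
        for name, length, cen in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{name}: non-positive length")
            if not 0 < cen < length:
                raise ValueError(f"{name}: centromere outside chromosome")
        if tuple(self.trinucleotide_freq.columns) != TRINUCLEOTIDES_32:
            raise ValueError("trinucleotide table must have the 32 canonical columns")
        sums = self.trinucleotide_freq.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("trinucleotide frequencies must sum to 1 per chromosome")

    @property
    def names(self) -> tuple:
        return tuple(c[0] for c in self.chromosomes)

    def length(self, chrom: str) -> int:
        for name, length, _ in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def centromere(self, chrom: str) -> int:
        for name, _, cen in self.chromosomes:
            if name == chrom:
                return cen
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(c[1] for c in self.chromosomes)


@dataclass
class GeneSetCollection:
    """Named gene sets (as read from GMT)."""

    sets: dict  # name -> tuple of genes
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {k: tuple(v) for k, v in self.sets.items()}

    def __getitem__(self, name: str) -> tuple:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list:
        return list(self.sets)

    def all_genes(self) -> set:
        out: set = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values with their scale."""

    values: pd.DataFrame  # genes (index) x samples (columns)
    scale: str = "TPM"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative expression values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass
class SignatureSet:
    """Signature probability profiles over a fixed channel order.

    ``profiles`` is signatures (rows) x channels (columns); every row is
    a probability vector.
    """

    profiles: pd.DataFrame
    provenance: str = "reference"  # or "extracted"

    def __post_init__(self) -> None:
        arr = self.profiles.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValueError("negative signature entries")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("signature rows must sum to 1")

    @property
    def names(self) -> list:
        return list(self.profiles.index)

    @property
    def k(self) -> int:
        return self.profiles.shape[0]

    @property
    def channels(self) -> list:
        return list(self.profiles.columns)


@dataclass
class KataegisLocus:
    """A localized hypermutation locus."""

    sample_id: str
    chrom: str
    start: int  # 1-based first mutation position
    end: int  # 1-based last mutation position (end > start)
    n_mut: int
    hypermutation_score: float  # locus density / chromosome density
    apobec_score: float  # fraction of member SNVs that are TpCpW C>T/C>G
    q_value: float
    kataegis_class: str  # "APOBEC" or "non-APOBEC"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("locus end must exceed start")
        if not 0 <= self.apobec_score <= 1:
            raise ValueError("apobec_score outside [0, 1]")


@dataclass(frozen=True)
class HrdScores:
    """Genomic-scar components of homologous recombination deficiency."""

    sample_id: str
    loh: int
    tai: int
    lst: int
    hrdetect_prob: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.loh, self.tai, self.lst) < 0:
            raise ValueError("negative HRD component")
        if self.hrdetect_prob is not None and not 0 <= self.hrdetect_prob <= 1:
            raise ValueError("HRDetect probability outside [0, 1]")

    @property
    def hrd_sum(self) -> int:
        return self.loh + self.tai + self.lst


@dataclass
class ComplexEventCall:
    """Per-chromosome complex-event evidence and call."""

    sample_id: str
    chrom: str
    region: tuple  # (start, end) bp of the largest interleaved cluster
    n_interleaved: int
    n_oscillations: int  # max two-state oscillation steps
    n_oscillations3: int  # max oscillation steps over <=3 states
    q_enrichment: float
    q_exponential: float
    q_joins: float
    criterion: Optional[str] = None  # "A", "B" or None
    called: bool = False
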