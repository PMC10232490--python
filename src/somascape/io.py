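"""Readers and writers for the standard file formats the pipeline touches.

Conventions
-----------
* VCF is one file per sample; the trinucleotide context travels in the
  INFO tag ``TNC`` (3-mer on the reported strand) so no reference FASTA
  is required. If ``TNC`` is absent a FASTA may be supplied instead.
* BEDPE starts are 0-based and converted to the internal 1-based
  breakend positions at this boundary.
* Segment, expression, clinical and signature tables are plain TSV.
* All readers reject malformed coordinates rather than coercing them;
  every writer produces files its own reader parses back identically.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .types import (
    ClinicalRecord,
    CnSegment,
    ExpressionMatrix,
    GeneSetCollection,
    SignatureSet,
    SnvRecord,
    SvRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_bedpe",
    "write_bedpe",
    "read_segments",
    "write_segments",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_signatures",
    "write_signatures",
    "read_catalogue",
    "write_catalogue",
]


def read_vcf(
    path, sample_id: Optional[str] = None, fasta: Optional[str] = None
) -> list[SnvRecord]:
    """Read somatic SNVs from a single-sample VCF.

    Only SNV lines are consumed; indels and multi-allelic lines are
    skipped with a logged count. Context comes from the ``TNC`` INFO tag,
    or from ``fasta`` when the tag is absent; with neither, a ValueError
    is raised.
    """
    path = str(path)
    if sample_id is None:
        with pysam.VariantFile(path) as vf:
            for rec in str(vf.header).splitlines():
                if rec.startswith("##sample="):
                    sample_id = rec.split("=", 1)[1]
                    break
        if sample_id is None:
            sample_id = Path(path).name.split(".")[0]
    ref_fa = pysam.FastaFile(fasta) if fasta else None
    records: list[SnvRecord] = []
    skipped = 0
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or set(ref + alt) - set("ACGT"):
                skipped += 1
                continue
            tnc = rec.info.get("TNC") if "TNC" in rec.info else None
            if tnc is None:
                if ref_fa is None:
                    raise ValueError(
                        f"{path}:{rec.pos}: no TNC tag and no FASTA supplied"
                    )
                tnc = ref_fa.fetch(rec.chrom, rec.pos - 2, rec.pos + 1).upper()
            records.append(
                SnvRecord.from_alleles(sample_id, rec.chrom, rec.pos, ref, alt, str(tnc))
            )
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV lines", path, skipped)
    if ref_fa is not None:
        ref_fa.close()
    read_vcf.last_skipped = skipped  # exposed for logging/tests
    return records


def write_vcf(records: Sequence[SnvRecord], path) -> None:
    """Write single-sample SNVs as VCF 4.2 with the context in INFO/TNC."""
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValueError("write_vcf writes one sample per file")
    sample = samples.pop() if samples else "NA"
    from .constants import reverse_complement

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##sample={sample}\n")
        fh.write(
            '##INFO=<ID=TNC,Number=1,Type=String,'
            'Description="Trinucleotide context on the reported strand">\n'
        )
        for chrom in sorted({r.chrom for r in records}):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in sorted(records, key=lambda x: (x.chrom, x.pos)):
            ctx = r.context3 if r.ref in "CT" else reverse_complement(r.context3)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\tTNC={ctx}\n"
            )


_BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "sv_type",
]


def read_bedpe(path) -> list[SvRecord]:
    """Read SVs from BEDPE (0-based starts; sample id in the name column,
    SV type in column 11)."""
    df = pd.read_csv(path, sep="\t", header=None, names=_BEDPE_COLS, comment="#")
    if df.empty:
        return []
    if (df[["start1", "start2"]].to_numpy() < 0).any():
        raise ValueError(f"{path}: negative coordinates")
    out = []
    for row in df.itertuples(index=False):
        pos1 = int(row.start1) + 1
        pos2 = int(row.start2) + 1
        out.append(
            SvRecord(str(row.name), str(row.chrom1), pos1, str(row.chrom2), pos2,
                     str(row.sv_type))
        )
    return out


def write_bedpe(svs: Sequence[SvRecord], path) -> None:
    rows = []
    for r in svs:
        rows.append([
            r.chrom1, r.pos1 - 1, r.pos1, r.chrom2, r.pos2 - 1, r.pos2,
            r.sample_id, ".", ".", ".", r.sv_type,
        ])
    pd.DataFrame(rows, columns=_BEDPE_COLS).to_csv(
        path, sep="\t", header=False, index=False
    )


_SEG_COLS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn", "subclonal_q"]


def read_segments(path) -> list[CnSegment]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_SEG_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not df.empty and (df[["start", "end"]].to_numpy() < 0).any():
        raise ValueError(f"{path}: negative coordinates")
    out = []
    for row in df.itertuples(index=False):
        q = None if pd.isna(row.subclonal_q) else float(row.subclonal_q)
        out.append(
            CnSegment(str(row.sample), str(row.chrom), int(row.start), int(row.end),
                      int(row.total_cn), int(row.minor_cn), q)
        )
    return out


def write_segments(segments: Sequence[CnSegment], path) -> None:
    rows = [
        [s.sample_id, s.chrom, s.start, s.end, s.total_cn, s.minor_cn,
         np.nan if s.subclonal_q is None else s.subclonal_q]
        for s in segments
    ]
    # q column stays float64 so the shortest-repr float writing round-trips
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False, na_rep="")


def read_expression(path, scale: str = "TPM") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    return ExpressionMatrix(df, scale=scale)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path) -> GeneSetCollection:
    sets, descriptions = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            name, desc, genes = parts[0], parts[1], parts[2:]
            sets[name] = tuple(g for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.sets.items():
            desc = sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


_CLIN_COLS = [
    "sample_id", "os_months", "os_event", "pfs_months", "pfs_event",
    "stage", "treatment", "pet_response",
]


def read_clinical(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CLIN_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        ClinicalRecord(
            str(r.sample_id), float(r.os_months), int(r.os_event),
            float(r.pfs_months), int(r.pfs_event), str(r.stage),
            str(r.treatment), str(r.pet_response),
        )
        for r in df.itertuples(index=False)
    ]


def write_clinical(records: Sequence[ClinicalRecord], path) -> None:
    rows = [
        [r.sample_id, r.os_months, r.os_event, r.pfs_months, r.pfs_event,
         r.stage, r.treatment, r.pet_response]
        for r in records
    ]
    pd.DataFrame(rows, columns=_CLIN_COLS).to_csv(path, sep="\t", index=False)


def read_signatures(path, provenance: str = "reference") -> SignatureSet:
    """Read a signature catalogue TSV (channels as rows, signatures as columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0).T
    df.index.name = None
    df.columns.name = None
    return SignatureSet(df, provenance=provenance)


def write_signatures(sigs: SignatureSet, path) -> None:
    sigs.profiles.T.to_csv(path, sep="\t", index_label="channel")


def read_catalogue(path) -> pd.DataFrame:
    """Read a mutation/SV catalogue TSV (channels as rows, samples as columns)."""
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_catalogue(catalogue: pd.DataFrame, path) -> None:
    catalogue.T.to_csv(path, sep="\t", index_label="channel")
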