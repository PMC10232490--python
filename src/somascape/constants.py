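"""Channel orderings shared across the pipeline.

All substitution channels are expressed on the pyrimidine strand: a
purine reference (G/A) is reverse-complemented together with its
flanking bases before classification, so every SNV maps onto one of six
substitution classes and one of 32 pyrimidine-centred trinucleotides.
"""

from __future__ import annotations

from itertools import product

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine-strand substitution classes, in conventional order.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 32 pyrimidine-centred trinucleotides (middle base C or T), lexicographic.
TRINUCLEOTIDES_32 = tuple(
    f"{five}{mid}{three}"
    for five in BASES
    for mid in ("C", "T")
    for three in BASES
)

#: 96 SNV channels, substitution-class major, flanks lexicographic minor,
#: written in the COSMIC-style "A[C>T]G" notation.
SNV_CHANNELS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

#: SV size bins in bp, half-open [low, high); sizes below 1 kb are clamped
#: into the first bin by the classifier.
SV_SIZE_BINS = (
    ("1-10kb", 1_000, 10_000),
    ("10-100kb", 10_000, 100_000),
    ("100kb-1Mb", 100_000, 1_000_000),
    ("1-10Mb", 1_000_000, 10_000_000),
    (">10Mb", 10_000_000, None),
)

SV_TYPES = ("DEL", "DUP", "INV", "TRA")

#: 32 rearrangement channels: {del,dup,inv} x 5 size bins x {clustered,
#: non-clustered}, then translocations x {clustered, non-clustered}.
SV_CHANNELS_32 = tuple(
    f"{svt}/{size}/{clust}"
    for svt in ("del", "dup", "inv")
    for size, _, _ in SV_SIZE_BINS
    for clust in ("clustered", "non-clustered")
) + ("tra/clustered", "tra/non-clustered")


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def normalize_substitution(ref: str, alt: str, context3: str) -> tuple[str, str]:
    """Map an SNV to its pyrimidine-strand (subst_class, context3).

    ``context3`` is the 3-base context on the strand on which ``ref`` is
    reported; its middle base must equal ``ref``.
    """
    ref, alt, context3 = ref.upper(), alt.upper(), context3.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context3) != 3 or context3[1] != ref:
        raise ValueError(f"context {context3!r} inconsistent with ref {ref!r}")
    if ref in ("G", "A"):
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        context3 = reverse_complement(context3)
    return f"{ref}>{alt}", context3


def snv_channel(subst_class: str, context3: str) -> str:
    """COSMIC-style channel label, e.g. ('C>T', 'ACA') -> 'A[C>T]A'."""
    if subst_class not in SUBSTITUTION_CLASSES:
        raise ValueError(f"unknown substitution class {subst_class!r}")
    if len(context3) != 3 or context3[1] != subst_class[0]:
        raise ValueError(f"context {context3!r} inconsistent with {subst_class!r}")
    return f"{context3[0]}[{subst_class}]{context3[2]}"
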