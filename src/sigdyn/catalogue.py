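"""Mutation catalogues: SBS-96 / ID-83 channel classification and counting.

Substitutions are folded to the pyrimidine-centred representation; indels
are left-aligned against the genome and classified with COSMIC precedence
(homopolymer / repeat first, microhomology only for deletions that are not
repeat-mediated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._channels import fold_pyrimidine, sbs_channel
from .genome import SyntheticGenome
from .io import SomaticVariant, ValidationError, canonical_channels

_FOLD_BASE = {"A": "T", "G": "C", "C": "C", "T": "T"}


@dataclass
class ContextualizedSNV:
    """An SNV with its SBS-96 channel and pyrimidine-oriented pentamer."""

    variant: SomaticVariant
    channel: str
    pentamer: str | None  # None near contig ends / ambiguous bases
    pyrimidine_strand: str  # strand carrying the mutated pyrimidine


def classify_snv(variant: SomaticVariant, genome: SyntheticGenome) -> ContextualizedSNV | None:
    """Classify an SNV into its trinucleotide channel.

    Returns None (caller counts a drop) when the trinucleotide context is
    ambiguous or truncated; raises ValidationError when the VCF REF does not
    match the genome.
    """
    if variant.kind != "snv":
        raise ValidationError("classify_snv expects an SNV")
    base = genome.base(variant.chrom, variant.pos)
    if base != variant.ref:
        raise ValidationError(
            f"{variant.chrom}:{variant.pos}: VCF ref {variant.ref!r} != genome {base!r}"
        )
    tri = genome.context(variant.chrom, variant.pos, 1)
    if tri is None or any(b not in "ACGT" for b in tri):
        return None
    channel, strand = sbs_channel(tri, variant.ref, variant.alt)
    penta = genome.context(variant.chrom, variant.pos, 2)
    if penta is None or any(b not in "ACGT" for b in penta):
        penta = None
    elif strand == "-":
        penta = fold_pyrimidine(penta)
    return ContextualizedSNV(variant, channel, penta, strand)


# ---------------------------------------------------------------------------
# indels
# ---------------------------------------------------------------------------

def normalize_indel(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal left-aligned representation of a VCF-style indel.

    Returns (event_start, deleted_seq, inserted_seq); exactly one of the
    sequences is non-empty. ``event_start`` is the 0-based position of the
    first deleted base, or the insertion point (base inserted *before* it).
    """
    # trim shared suffix, then shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 0 and len(alt) > 0 and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    if ref and alt:
        raise ValidationError(f"not a simple indel after trimming: {ref}>{alt}")
    if ref:  # deletion of `ref` at pos
        start, allele = pos, ref
        while start > 0 and seq[start - 1] == allele[-1]:
            allele = seq[start - 1] + allele[:-1]
            start -= 1
        return start, allele, ""
    start, allele = pos, alt  # insertion of `alt` before pos
    while start > 0 and seq[start - 1] == allele[-1]:
        allele = seq[start - 1] + allele[:-1]
        start -= 1
    return start, "", allele


def _size_bin(length: int) -> int:
    return min(length, 5)


def classify_indel(variant: SomaticVariant, genome: SyntheticGenome) -> str | None:
    """ID-83 channel of an indel; None when it overlaps a contig end.

    1-bp events are labelled by pyrimidine-folded base and homopolymer run
    length; longer events by repeat copies of the indel sequence; deletions
    that are not repeat-mediated are checked for flanking microhomology.
    """
    seq = genome.sequences[variant.chrom]
    start, deleted, inserted = normalize_indel(seq, variant.pos, variant.ref, variant.alt)
    allele = deleted or inserted
    length = len(allele)
    end = start + (len(deleted) if deleted else 0)
    if start < 0 or end + 6 * length > len(seq) or start < length:
        return None  # too close to a contig end to classify
    if any(b not in "ACGT" for b in allele):
        return None

    if length == 1:
        b = _FOLD_BASE[allele]
        if deleted:
            run = 1
            while end + (run - 1) < len(seq) and seq[end + run - 1] == allele:
                run += 1
            # run counts the deleted base plus following copies
            return f"1:Del:{b}:{min(run, 6) - 1}"
        run = 0
        while start + run < len(seq) and seq[start + run] == allele:
            run += 1
        return f"1:Ins:{b}:{min(run, 5)}"

    size = _size_bin(length)
    if deleted:
        copies = 1
        while seq[start + copies * length : start + (copies + 1) * length] == allele:
            copies += 1
        if copies >= 2:
            return f"{size}:Del:R:{min(copies, 6) - 1}"
        # microhomology: prefix of the deleted sequence recurring right of it
        hom = 0
        while hom < length - 1 and seq[end + hom] == allele[hom]:
            hom += 1
        if hom >= 1:
            caps = {2: 1, 3: 2, 4: 3, 5: 5}
            return f"{size}:Del:M:{min(hom, caps[size])}"
        return f"{size}:Del:R:0"
    copies = 0
    while seq[start + copies * length : start + (copies + 1) * length] == allele:
        copies += 1
    return f"{size}:Ins:R:{min(copies, 5)}"


# ---------------------------------------------------------------------------
# catalogues / burden
# ---------------------------------------------------------------------------

def classify_sample_snvs(
    variants: list[SomaticVariant], genome: SyntheticGenome
) -> tuple[list[ContextualizedSNV], int]:
    """Classify all SNVs of one sample; returns (classified, n_dropped)."""
    out, dropped = [], 0
    for v in variants:
        if v.kind != "snv":
            continue
        c = classify_snv(v, genome)
        if c is None:
            dropped += 1
        else:
            out.append(c)
    return out, dropped


def build_catalogue(
    variants_by_sample: dict[str, list[SomaticVariant]],
    genome: SyntheticGenome,
    kind: str = "sbs96",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count variants into a samples x channels catalogue.

    Returns (catalogue, dropped) where ``dropped`` counts unclassifiable
    variants per sample. Row sums plus drops conserve the input counts of
    the relevant variant kind. Samples with no variants keep a zero row.
    """
    channels = canonical_channels(kind)
    idx = {c: i for i, c in enumerate(channels)}
    counts = np.zeros((len(variants_by_sample), len(channels)), dtype=np.int64)
    dropped: dict[str, int] = {}
    for si, (sample, variants) in enumerate(variants_by_sample.items()):
        ndrop = 0
        for v in variants:
            if kind == "sbs96":
                if v.kind != "snv":
                    continue
                c = classify_snv(v, genome)
                chan = c.channel if c is not None else None
            else:
                if v.kind == "snv":
                    continue
                chan = classify_indel(v, genome)
            if chan is None:
                ndrop += 1
            else:
                counts[si, idx[chan]] += 1
        dropped[sample] = ndrop
    return (
        pd.DataFrame(counts, index=list(variants_by_sample), columns=list(channels)),
        dropped,
    )


def tmb(variants: list[SomaticVariant], min_alt_reads: int = 3) -> dict[str, int]:
    """Mutation burden counts {snvs, indels, total} after read-support filter."""
    kept = [v for v in variants if v.alt_reads >= min_alt_reads]
    n_snv = sum(1 for v in kept if v.kind == "snv")
    return {"snvs": n_snv, "indels": len(kept) - n_snv, "total": len(kept)}
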