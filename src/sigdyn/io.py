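"""Readers and writers for the external formats touched by the pipeline.

Coordinate conventions: everything is 0-based half-open **internally**;
conversions happen only here, at the I/O boundary. VCF positions are 1-based
on disk; copy-number segment TSVs are 1-based inclusive on disk; BED is
0-based half-open on disk (and therefore passes through unchanged).

Readers validate rather than coerce: malformed headers, missing depth
fields, overlapping segments or badly normalized signature matrices raise
:class:`FormatError` / :class:`ValidationError` instead of being silently
repaired.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._channels import ID83_CHANNELS, SBS96_CHANNELS


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A file parses but violates a semantic invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SomaticVariant:
    """One somatic call. ``pos`` is 0-based (internal convention).

    ``kind`` is one of {"snv", "insertion", "deletion"}; ``consequence`` is
    the upstream annotation string if present (never computed here).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int
    ref_reads: int
    sample_id: str = ""
    consequence: str | None = None

    @property
    def kind(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "snv"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def vaf(self) -> float:
        return self.alt_reads / (self.alt_reads + self.ref_reads)


@dataclass
class CopyNumberSegment:
    """Allele-specific copy-number segment, 0-based half-open internally."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_major: int
    n_minor: int

    def __post_init__(self):
        if self.n_major < self.n_minor:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: n_major < n_minor"
            )
        if self.end <= self.start:
            raise ValidationError(f"segment {self.chrom}:{self.start}-{self.end}: empty")

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor


@dataclass
class SamplePurityPloidy:
    sample_id: str
    purity: float
    ploidy: float

    def __post_init__(self):
        if not 0.0 < self.purity <= 1.0:
            raise ValidationError(f"{self.sample_id}: purity {self.purity} outside (0, 1]")
        if self.ploidy <= 0:
            raise ValidationError(f"{self.sample_id}: ploidy must be positive")


@dataclass
class SignatureReference:
    """Reference signature matrix in COSMIC layout.

    ``matrix`` is channels x signatures (rows in canonical channel order,
    each signature column summing to 1).
    """

    matrix: pd.DataFrame
    kind: str  # "sbs96" or "id83"

    @property
    def channels(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def signatures(self) -> list[str]:
        return list(self.matrix.columns)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


def canonical_channels(kind: str) -> tuple[str, ...]:
    if kind == "sbs96":
        return SBS96_CHANNELS
    if kind == "id83":
        return ID83_CHANNELS
    raise ValueError(f"unknown catalogue kind {kind!r}")


def make_signature_reference(matrix: pd.DataFrame, kind: str, tol: float = 1e-3) -> SignatureReference:
    """Validate, reorder to canonical channel order and renormalize."""
    channels = canonical_channels(kind)
    unknown = set(matrix.index) - set(channels)
    if unknown:
        raise FormatError(f"unknown channel labels: {sorted(unknown)[:5]}")
    if set(matrix.index) != set(channels):
        missing = sorted(set(channels) - set(matrix.index))
        raise FormatError(f"missing channel labels, e.g. {missing[:5]}")
    m = matrix.reindex(list(channels)).astype(float)
    if (m.to_numpy() < 0).any():
        raise ValidationError("negative signature probabilities")
    sums = m.sum(axis=0)
    off = sums[(sums - 1.0).abs() > tol]
    if len(off):
        raise ValidationError(f"signature columns do not sum to 1: {dict(off.round(4))}")
    return SignatureReference(matrix=m / sums, kind=kind)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    sample_id: str | None = None,
    min_alt_reads: int = 3,
    keep_nonpass: bool = False,
) -> list[SomaticVariant]:
    """Read somatic calls from a VCF (v4.2+) with AD allelic depths.

    One record is returned per ALT allele (multi-allelic sites are split).
    Records whose FILTER is not PASS are excluded unless ``keep_nonpass``.
    Calls with fewer than ``min_alt_reads`` supporting reads are dropped
    (minimal read support; default 3). The tumour sample column is the one
    named ``sample_id``, or the only/first sample if not given.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    samples = vcf.samples
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    if sample_id is None:
        col = 0
        sample_id = samples[0]
    else:
        if sample_id not in samples:
            raise FormatError(f"{path}: sample {sample_id!r} not in VCF ({samples})")
        col = samples.index(sample_id)

    out: list[SomaticVariant] = []
    for rec in vcf:
        if rec.FILTER is not None and not keep_nonpass:
            continue
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks AD allelic depths"
            )
        depths = ad[col]
        ref_reads = int(depths[0])
        csq = rec.INFO.get("CSQ")
        for ai, alt in enumerate(rec.ALT):
            alt_reads = int(depths[1 + ai]) if len(depths) > 1 + ai else 0
            if alt_reads + ref_reads <= 0:
                raise FormatError(
                    f"{path}: record {rec.CHROM}:{rec.POS} has zero total depth"
                )
            if alt_reads < min_alt_reads:
                continue
            out.append(
                SomaticVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS - 1,
                    ref=rec.REF,
                    alt=alt,
                    alt_reads=alt_reads,
                    ref_reads=ref_reads,
                    sample_id=sample_id,
                    consequence=csq,
                )
            )
    return out


def write_vcf(
    variants: list[SomaticVariant],
    path: str | Path,
    contig_lengths: dict[str, int],
    sample_id: str = "TUMOUR",
) -> None:
    """Write a minimal VCF v4.2 with AD depths in one tumour sample column."""
    order = {c: i for i, c in enumerate(contig_lengths)}
    variants = sorted(variants, key=lambda v: (order.get(v.chrom, 10**9), v.pos))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for v in variants:
            info = f"CSQ={v.consequence}" if v.consequence else "."
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{info}"
                f"\tGT:AD\t0/1:{v.ref_reads},{v.alt_reads}\n"
            )


# ---------------------------------------------------------------------------
# copy-number segments / purity-ploidy
# ---------------------------------------------------------------------------

_SEG_COLS = ["sample", "chrom", "start", "end", "nMajor", "nMinor"]


def read_segments(path: str | Path) -> list[CopyNumberSegment]:
    """Read an ASCAT-style TSV (sample, chrom, start, end, nMajor, nMinor).

    Coordinates are 1-based inclusive on disk and converted to 0-based
    half-open. Overlapping segments within a sample are a validation error.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SEG_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing segment columns {missing}")
    segs = [
        CopyNumberSegment(
            sample_id=str(r.sample),
            chrom=str(r.chrom),
            start=int(r.start) - 1,
            end=int(r.end),
            n_major=int(r.nMajor),
            n_minor=int(r.nMinor),
        )
        for r in df.itertuples()
    ]
    _check_overlaps(segs)
    return segs


def _check_overlaps(segs: list[CopyNumberSegment]) -> None:
    by_key: dict[tuple[str, str], list[CopyNumberSegment]] = {}
    for s in segs:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    offenders = []
    for group in by_key.values():
        group.sort(key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                offenders.append((a.sample_id, a.chrom, a.start, a.end, b.start, b.end))
    if offenders:
        raise ValidationError(f"overlapping copy-number segments: {offenders[:5]}")


def write_segments(segs: list[CopyNumberSegment], path: str | Path) -> None:
    rows = [
        (s.sample_id, s.chrom, s.start + 1, s.end, s.n_major, s.n_minor) for s in segs
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)


def read_purity_table(path: str | Path) -> dict[str, SamplePurityPloidy]:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "purity", "ploidy"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return {
        str(r.sample): SamplePurityPloidy(str(r.sample), float(r.purity), float(r.ploidy))
        for r in df.itertuples()
    }


def write_purity_table(table: dict[str, SamplePurityPloidy], path: str | Path) -> None:
    rows = [(p.sample_id, p.purity, p.ploidy) for p in table.values()]
    pd.DataFrame(rows, columns=["sample", "purity", "ploidy"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals (0-based half-open; passes through unchanged)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED line has fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValidationError(f"{path}:{ln}: empty BED interval")
            out.append((chrom, start, end))
    return out


def read_dyads_bed(path: str | Path) -> dict[str, np.ndarray]:
    """Read nucleosome dyad centres (single-base BED records)."""
    dyads: dict[str, list[int]] = {}
    for chrom, start, _end in read_bed(path):
        dyads.setdefault(chrom, []).append(start)
    return {c: np.array(sorted(p), dtype=np.int64) for c, p in dyads.items()}


# ---------------------------------------------------------------------------
# signature matrices / exposures / catalogues
# ---------------------------------------------------------------------------

def read_signature_matrix(path: str | Path, kind: str = "sbs96") -> SignatureReference:
    """TSV with channel labels in the first column, signatures in the rest."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no signature columns")
    return make_signature_reference(df, kind)


def write_signature_matrix(ref: SignatureReference, path: str | Path) -> None:
    ref.matrix.rename_axis("Type").to_csv(path, sep="\t")


def read_exposures(path: str | Path) -> pd.DataFrame:
    """Exposure TSV: samples in rows (index), signatures in columns."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_exposures(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("sample").to_csv(path, sep="\t")


def read_catalogue(path: str | Path) -> pd.DataFrame:
    """Catalogue TSV in COSMIC orientation (channels x samples) -> samples x channels."""
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_catalogue(catalogue: pd.DataFrame, path: str | Path) -> None:
    catalogue.T.rename_axis("Type").to_csv(path, sep="\t")


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample" not in df.columns or "stage" not in df.columns:
        raise FormatError(f"{path}: clinical table needs 'sample' and 'stage' columns")
    return df.set_index("sample")
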