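"""Synthetic genome generation and sequence context indexing.

The synthetic genome is an i.i.d.-base sequence at a requested GC content,
annotated with nucleosome dyad positions, genes and replication domains. It
stands in for a real reference assembly plus nucleosome map so that every
downstream statistic (catalogues, periodicity, strand bias) can be exercised
with known ground truth and no external downloads. All coordinates are
0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._channels import fold_pyrimidine


class ArgumentError(ValueError):
    """Invalid argument to a generator or analysis routine."""


@dataclass
class GeneInterval:
    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    name: str = ""


@dataclass
class ReplicationDomain:
    chrom: str
    start: int
    end: int
    direction: str  # "left" or "right" (direction of fork travel)


@dataclass
class SyntheticGenome:
    """A small self-contained genome with chromatin annotations.

    Attributes
    ----------
    sequences : dict of chromosome name -> DNA string.
    dyads : dict of chromosome name -> sorted array of dyad centre positions.
    genes : list of GeneInterval.
    repl_domains : list of ReplicationDomain.
    """

    sequences: dict[str, str]
    dyads: dict[str, np.ndarray]
    genes: list[GeneInterval] = field(default_factory=list)
    repl_domains: list[ReplicationDomain] = field(default_factory=list)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def context(self, chrom: str, pos: int, flank: int) -> str | None:
        """Genome-strand context of width ``2*flank+1`` centred on ``pos``.

        Returns None when the window runs off the contig.
        """
        seq = self.sequences[chrom]
        if pos - flank < 0 or pos + flank + 1 > len(seq):
            return None
        return seq[pos - flank : pos + flank + 1]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]

    # -- trinucleotide index -------------------------------------------------
    def trinuc_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Map each pyrimidine-folded trinucleotide to its genomic positions.

        Returns a dict ``context -> (chrom_codes, positions)`` covering every
        internal position of every chromosome (positions whose window would
        contain an N are skipped). Cached after the first call.
        """
        if getattr(self, "_trinuc_index", None) is None:
            self._trinuc_index = _build_trinuc_index(self)
        return self._trinuc_index

    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_dyads_bed(self, path: str | Path) -> None:
        """Dyads as 0-based half-open single-base BED intervals."""
        with open(path, "w") as fh:
            for chrom, pos in self.dyads.items():
                for p in pos:
                    fh.write(f"{chrom}\t{p}\t{p + 1}\n")


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _build_trinuc_index(genome: SyntheticGenome) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for ci, (chrom, seq) in enumerate(genome.sequences.items()):
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        # map ACGT to 0..3, anything else to 255
        lut = np.full(256, 255, dtype=np.uint8)
        for b, v in _BASE_CODE.items():
            lut[ord(b)] = v
        c = lut[codes]
        valid = (c[:-2] < 4) & (c[1:-1] < 4) & (c[2:] < 4)
        key = c[:-2].astype(np.int32) * 16 + c[1:-1].astype(np.int32) * 4 + c[2:].astype(np.int32)
        pos = np.nonzero(valid)[0] + 1  # centre positions
        key = key[valid]
        order = np.argsort(key, kind="stable")
        key, pos = key[order], pos[order]
        bounds = np.searchsorted(key, np.arange(65))
        for k in range(64):
            if bounds[k] == bounds[k + 1]:
                continue
            tri = "ACGT"[k >> 4] + "ACGT"[(k >> 2) & 3] + "ACGT"[k & 3]
            folded = fold_pyrimidine(tri)
            out.setdefault(folded, []).append(
                (np.full(bounds[k + 1] - bounds[k], ci, dtype=np.int32), pos[bounds[k] : bounds[k + 1]].astype(np.int64))
            )
    return {
        tri: (np.concatenate([c for c, _ in parts]), np.concatenate([p for _, p in parts]))
        for tri, parts in out.items()
    }


def generate_genome(
    n_chroms: int = 1,
    chrom_length: int = 1_000_000,
    gc_fraction: float = 0.4,
    dyad_spacing: int = 197,
    seed: int = 0,
    dyad_jitter: int = 10,
    gene_size: int = 5_000,
    repl_domain_size: int = 50_000,
) -> SyntheticGenome:
    """Generate a deterministic synthetic genome.

    Bases are i.i.d. at the requested GC fraction. Nucleosome dyads are placed
    every ``dyad_spacing`` bp (147 bp core + 50 bp linker by default) with
    integer jitter drawn uniformly from ``[-dyad_jitter, dyad_jitter]``. Genes
    tile ~50% of each chromosome in alternating-strand blocks of
    ``gene_size`` bp separated by equally sized gaps; replication domains
    tile the chromosome with alternating fork direction.
    """
    if n_chroms <= 0 or chrom_length <= 0 or dyad_spacing <= 0:
        raise ArgumentError("n_chroms, chrom_length and dyad_spacing must be positive")
    if not 0.0 < gc_fraction < 1.0:
        raise ArgumentError("gc_fraction must lie in (0, 1)")
    if chrom_length < 10 * dyad_spacing:
        raise ArgumentError("chrom_length must be at least 10 x dyad_spacing")

    rng = np.random.default_rng(seed)
    probs = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    margin = 100  # keep dyad windows clear of contig ends

    sequences: dict[str, str] = {}
    dyads: dict[str, np.ndarray] = {}
    genes: list[GeneInterval] = []
    domains: list[ReplicationDomain] = []
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_length, p=probs)
        sequences[chrom] = bases.tobytes().decode()

        centres = np.arange(margin, chrom_length - margin, dyad_spacing, dtype=np.int64)
        if dyad_jitter > 0:
            centres = centres + rng.integers(-dyad_jitter, dyad_jitter + 1, size=centres.size)
        centres = np.unique(np.clip(centres, margin, chrom_length - margin - 1))
        dyads[chrom] = centres

        strand = "+"
        for gi, start in enumerate(range(0, chrom_length - gene_size, 2 * gene_size)):
            genes.append(
                GeneInterval(chrom, start, start + gene_size, strand, name=f"{chrom}_g{gi}")
            )
            strand = "-" if strand == "+" else "+"

        direction = "right"
        for start in range(0, chrom_length, repl_domain_size):
            domains.append(
                ReplicationDomain(chrom, start, min(start + repl_domain_size, chrom_length), direction)
            )
            direction = "left" if direction == "right" else "right"

    return SyntheticGenome(sequences=sequences, dyads=dyads, genes=genes, repl_domains=domains)
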