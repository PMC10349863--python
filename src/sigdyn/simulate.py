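"""Synthetic cohort generator with known ground truth.

Emulates a whole-genome-sequenced cohort spanning Barrett Oesophagus,
primary tumour and metastatic stages: per-sample SNV/indel calls drawn from
known signature mixtures and clonal structure, allele-specific copy-number
segments consistent with purity/ploidy, optional nucleosome-periodic
positional modulation of the mutation rate, and planted DDR gene events.
Every stochastic choice derives from one seed, so a cohort is reproducible
file-for-file.

Mutations are generated channel-first: compartment (clone) ~ clone mutation
fractions, signature ~ that compartment's exposures, channel ~ the
signature's profile, position ~ uniform over genomic sites matching the
channel's context. When a periodic configuration names the signature,
positions within +-73 bp of a nucleosome dyad are accepted with probability
proportional to 1 + amplitude*cos(2*pi*d/period) (d = signed distance to
the dyad), which plants a helical-repeat periodicity recoverable by the
periodicity pipeline. Read counts are binomial at the expected VAF implied
by purity, local copy number, multiplicity and clone CCF.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._channels import revcomp
from .catalogue import classify_indel
from .genome import SyntheticGenome, generate_genome
from .io import (
    CopyNumberSegment,
    SamplePurityPloidy,
    SignatureReference,
    SomaticVariant,
    write_purity_table,
    write_segments,
    write_vcf,
)
from .references import (
    BULK_HELICAL_PERIOD_BP,
    SBS17B_HELICAL_PERIOD_BP,
    signature_reference,
)


class SimulationError(RuntimeError):
    """A requested mutation class cannot be realized on the genome."""


@dataclass
class PeriodicConfig:
    """Plant a nucleosome-periodic positional bias for one signature."""

    signature: str
    period_bp: float = BULK_HELICAL_PERIOD_BP
    amplitude: float = 0.6

    def __post_init__(self):
        if not 0.0 <= self.amplitude < 1.0:
            raise ValueError("amplitude must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth for one synthetic sample."""

    sample_id: str
    stage: str  # barrett | primary | metastasis
    purity: float
    ploidy: float
    wgd: bool = False
    # compartment ("clonal"/"subclonal") -> signature -> fraction
    exposures: dict[str, dict[str, float]] = field(default_factory=dict)
    id_exposures: dict[str, dict[str, float]] = field(default_factory=dict)
    # list of (ccf, mutation fraction); exactly one clone with ccf == 1
    clone_table: list[tuple[float, float]] = field(default_factory=lambda: [(1.0, 1.0)])
    early_fraction: float = 0.5  # clonal mutations at multiplicity >= 2 when WGD
    planted_period: PeriodicConfig | None = None
    planted_cn_events: list[tuple[str, int, int, int, int]] = field(default_factory=list)
    # (gene_name, event) with event in {SNV_indel, AMP, DEL, LOH}
    planted_pathway_hits: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        for comp, exp in list(self.exposures.items()) + list(self.id_exposures.items()):
            s = sum(exp.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"{self.sample_id}/{comp}: exposures sum to {s}")
        ccfs = [c for c, _ in self.clone_table]
        if not any(abs(c - 1.0) < 1e-9 for c in ccfs):
            raise ValueError("clone_table must contain a clone with CCF = 1")
        if any(not 0 < c <= 1 for c in ccfs):
            raise ValueError("clone CCFs must lie in (0, 1]")
        if abs(sum(f for _, f in self.clone_table) - 1.0) > 1e-6:
            raise ValueError("clone mutation fractions must sum to 1")


# ---------------------------------------------------------------------------
# copy-number profile
# ---------------------------------------------------------------------------

def _baseline_cn(truth: TruthRecord, genome: SyntheticGenome) -> list[CopyNumberSegment]:
    base_major, base_minor = (2, 2) if truth.wgd else (1, 1)
    events = {}
    for chrom, start, end, nmaj, nmin in truth.planted_cn_events:
        events.setdefault(chrom, []).append((start, end, nmaj, nmin))
    segs: list[CopyNumberSegment] = []
    for chrom, length in genome.chrom_lengths.items():
        cuts = [(0, length, base_major, base_minor)]
        for start, end, nmaj, nmin in sorted(events.get(chrom, [])):
            new = []
            for s, e, ma, mi in cuts:
                if e <= start or s >= end:
                    new.append((s, e, ma, mi))
                    continue
                if s < start:
                    new.append((s, start, ma, mi))
                new.append((max(s, start), min(e, end), nmaj, nmin))
                if e > end:
                    new.append((end, e, ma, mi))
            cuts = new
        segs += [
            CopyNumberSegment(truth.sample_id, chrom, s, e, ma, mi) for s, e, ma, mi in cuts
        ]
    return segs


class _SegmentLookup:
    def __init__(self, segs: list[CopyNumberSegment]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[CopyNumberSegment]]] = {}
        for s in segs:
            self._by_chrom.setdefault(s.chrom, ([], [], []))  # type: ignore[arg-type]
        tmp: dict[str, list[CopyNumberSegment]] = {}
        for s in segs:
            tmp.setdefault(s.chrom, []).append(s)
        for chrom, group in tmp.items():
            group.sort(key=lambda s: s.start)
            starts = np.array([g.start for g in group])
            ends = np.array([g.end for g in group])
            self._by_chrom[chrom] = (starts, ends, group)

    def find(self, chrom: str, pos: int) -> CopyNumberSegment | None:
        if chrom not in self._by_chrom:
            return None
        starts, ends, group = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return group[i]
        return None


# ---------------------------------------------------------------------------
# read-count model
# ---------------------------------------------------------------------------

def expected_vaf(purity: float, n_major: int, n_minor: int, multiplicity: int, ccf: float) -> float:
    """Expected VAF of a mutation on ``multiplicity`` copies in cells at ``ccf``."""
    denom = purity * (n_major + n_minor) + (1.0 - purity) * 2.0
    return purity * multiplicity * ccf / denom


def _draw_reads(rng, vaf: float, depth: int) -> tuple[int, int]:
    """Binomial alt/ref reads at Poisson-distributed depth, conditioned on
    at least one supporting read (an uncalled site is never emitted)."""
    for _ in range(1000):
        d = max(int(rng.poisson(depth)), 2)
        alt = int(rng.binomial(d, min(vaf, 1.0)))
        if alt >= 1:
            return alt, d - alt
    return 1, max(int(rng.poisson(depth)), 2) - 1


# ---------------------------------------------------------------------------
# position sampling
# ---------------------------------------------------------------------------

class _PositionSampler:
    """Draws genomic positions for SBS channels, with optional periodic
    acceptance weighting around nucleosome dyads."""

    def __init__(self, genome: SyntheticGenome):
        self.genome = genome
        self.index = genome.trinuc_index()
        self.chroms = genome.chrom_names()

    def sample(self, rng, channel: str, periodic: PeriodicConfig | None) -> tuple[str, int]:
        tri = channel[0] + channel[2] + channel[6]
        if tri not in self.index:
            raise SimulationError(f"no genomic position matches channel {channel}")
        chrom_codes, positions = self.index[tri]
        n = len(positions)
        while True:
            i = int(rng.integers(n))
            chrom = self.chroms[chrom_codes[i]]
            pos = int(positions[i])
            if periodic is None:
                return chrom, pos
            dyads = self.genome.dyads[chrom]
            j = int(np.searchsorted(dyads, pos))
            d = None
            for k in (j - 1, j):
                if 0 <= k < len(dyads) and abs(pos - dyads[k]) <= 73:
                    d = pos - dyads[k]
                    break
            if d is None:
                w = 1.0
            else:
                w = 1.0 + periodic.amplitude * np.cos(2 * np.pi * d / periodic.period_bp)
            if rng.random() * (1.0 + periodic.amplitude) < w:
                return chrom, pos


class _HomopolymerIndex:
    """Run-length index of homopolymers, for direct 1-bp indel site lookup."""

    def __init__(self, genome: SyntheticGenome):
        self.runs: dict[tuple[str, int], list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                base = seq[s]
                if base not in "ACGT":
                    continue
                run = min(int(e - s), 6)
                self.runs.setdefault((base, run), []).append((chrom, int(s)))

    def sites(self, base: str, run: int) -> list[tuple[str, int]]:
        return self.runs.get((base, run), [])


def _indel_candidate(
    rng, genome: SyntheticGenome, channel: str, homo: _HomopolymerIndex
) -> SomaticVariant | None:
    """Propose one indel realizing ``channel`` (verified by classify_indel)."""
    size_s, op, sub, num_s = channel.split(":")
    size, num = int(size_s), int(num_s)
    chroms = genome.chrom_names()
    if size == 1:
        # direct lookup in the homopolymer index; base folded => both strands
        want_run = num + 1 if op == "Del" else num
        bases = [sub, revcomp(sub)]
        pool: list[tuple[str, int, str]] = []
        runs = range(want_run, 7) if want_run >= 6 or (op == "Ins" and num == 5) else [want_run]
        if op == "Ins" and num == 0:
            # insertion not adjacent to the same base: probe random positions
            for _ in range(200):
                chrom = chroms[int(rng.integers(len(chroms)))]
                seq = genome.sequences[chrom]
                pos = int(rng.integers(10, len(seq) - 10))
                b = bases[int(rng.integers(2))]
                v = _make_insertion(genome, chrom, pos, b)
                if v is not None and classify_indel(v, genome) == channel:
                    return v
            return None
        for b in bases:
            for r in runs:
                pool += [(c, p, b) for c, p in homo.sites(b, r)]
        if not pool:
            return None
        chrom, start, b = pool[int(rng.integers(len(pool)))]
        if op == "Del":
            v = _make_deletion(genome, chrom, start, 1)
        else:
            v = _make_insertion(genome, chrom, start, b)
        if v is not None and classify_indel(v, genome) == channel:
            return v
        return None
    # multi-bp: rejection probing with the classifier as acceptance oracle
    chrom = chroms[int(rng.integers(len(chroms)))]
    seq = genome.sequences[chrom]
    pos = int(rng.integers(20, len(seq) - 60))
    if op == "Del":
        v = _make_deletion(genome, chrom, pos, size)
    else:
        if num == 0:  # inserted sequence must not duplicate the flanks
            unit = "".join("ACGT"[int(b)] for b in rng.integers(0, 4, size))
        else:
            unit = seq[pos : pos + size]
        v = _make_insertion(genome, chrom, pos, unit)
    if v is not None and classify_indel(v, genome) == channel:
        return v
    return None


def _make_deletion(genome: SyntheticGenome, chrom: str, start: int, length: int) -> SomaticVariant | None:
    seq = genome.sequences[chrom]
    if start < 1 or start + length >= len(seq):
        return None
    anchor = seq[start - 1]
    ref = seq[start - 1 : start + length]
    if any(b not in "ACGT" for b in ref):
        return None
    return SomaticVariant(chrom, start - 1, ref, anchor, alt_reads=1, ref_reads=1)


def _make_insertion(genome: SyntheticGenome, chrom: str, pos: int, inserted: str) -> SomaticVariant | None:
    seq = genome.sequences[chrom]
    if pos < 1 or pos >= len(seq):
        return None
    anchor = seq[pos - 1]
    if anchor not in "ACGT" or any(b not in "ACGT" for b in inserted):
        return None
    return SomaticVariant(chrom, pos - 1, anchor, anchor + inserted, alt_reads=1, ref_reads=1)


# ---------------------------------------------------------------------------
# sample simulation
# ---------------------------------------------------------------------------

_INDEL_PROBE_BUDGET = 200_000


def simulate_sample(
    genome: SyntheticGenome,
    truth: TruthRecord,
    n_snvs: int,
    n_indels: int = 0,
    depth: int = 50,
    periodic: PeriodicConfig | None = None,
    seed: int = 0,
    sbs_reference: SignatureReference | None = None,
    id_reference: SignatureReference | None = None,
) -> tuple[list[SomaticVariant], list[CopyNumberSegment]]:
    """Draw one sample's somatic calls and copy-number profile.

    Exactly ``n_snvs`` SNVs and ``n_indels`` indels are emitted, plus one
    extra variant per planted SNV-class pathway hit. ``periodic`` defaults
    to ``truth.planted_period``.
    """
    rng = np.random.default_rng(seed)
    if periodic is None:
        periodic = truth.planted_period
    sbs_ref = sbs_reference if sbs_reference is not None else signature_reference("sbs96")
    id_ref = id_reference if id_reference is not None else signature_reference("id83")

    segments = _baseline_cn(truth, genome)
    lookup = _SegmentLookup(segments)
    sampler = _PositionSampler(genome)

    clone_ccfs = np.array([c for c, _ in truth.clone_table])
    clone_fracs = np.array([f for _, f in truth.clone_table])

    def compartment_of(ccf: float) -> str:
        return "clonal" if abs(ccf - 1.0) < 1e-9 else "subclonal"

    def exposures_for(table: dict[str, dict[str, float]], comp: str) -> dict[str, float]:
        if comp in table:
            return table[comp]
        if "clonal" in table:
            return table["clonal"]
        raise ValueError(f"{truth.sample_id}: no exposures for compartment {comp!r}")

    variants: list[SomaticVariant] = []

    def finish(chrom: str, pos: int, ref: str, alt: str, ccf: float, consequence=None):
        seg = lookup.find(chrom, pos)
        n_major, n_minor = (seg.n_major, seg.n_minor) if seg else (1, 1)
        if compartment_of(ccf) == "clonal" and n_major >= 2 and rng.random() < truth.early_fraction:
            m = 2
        else:
            m = 1
        m = min(m, max(n_major, 1))
        vaf = expected_vaf(truth.purity, n_major, n_minor, m, ccf)
        alt_reads, ref_reads = _draw_reads(rng, vaf, depth)
        variants.append(
            SomaticVariant(chrom, pos, ref, alt, alt_reads, ref_reads, truth.sample_id, consequence)
        )

    # --- SNVs ---
    sbs_cols = {s: sbs_ref.matrix[s].to_numpy() for s in sbs_ref.signatures}
    clone_idx = rng.choice(len(clone_ccfs), size=n_snvs, p=clone_fracs)
    for ci in clone_idx:
        ccf = float(clone_ccfs[ci])
        exp = exposures_for(truth.exposures, compartment_of(ccf))
        sigs = list(exp)
        sig = sigs[int(rng.choice(len(sigs), p=np.array([exp[s] for s in sigs])))]
        probs = sbs_cols[sig]
        chan = sbs_ref.channels[int(rng.choice(len(probs), p=probs))]
        per = periodic if (periodic is not None and periodic.signature == sig) else None
        chrom, pos = sampler.sample(rng, chan, per)
        # channel is pyrimidine-centred; emit on the genome strand
        ref_base = genome.base(chrom, pos)
        alt_base = chan[4] if ref_base == chan[2] else revcomp(chan[4])
        finish(chrom, pos, ref_base, alt_base, ccf)

    # --- indels ---
    if n_indels > 0:
        homo = _HomopolymerIndex(genome)
        id_table = truth.id_exposures or {"clonal": _default_id_exposures()}
        clone_idx = rng.choice(len(clone_ccfs), size=n_indels, p=clone_fracs)
        for ci in clone_idx:
            ccf = float(clone_ccfs[ci])
            exp = exposures_for(id_table, compartment_of(ccf))
            sigs = list(exp)
            sig = sigs[int(rng.choice(len(sigs), p=np.array([exp[s] for s in sigs])))]
            probs = id_ref.matrix[sig].to_numpy()
            chan = id_ref.channels[int(rng.choice(len(probs), p=probs))]
            v = None
            for _ in range(_INDEL_PROBE_BUDGET):
                v = _indel_candidate(rng, genome, chan, homo)
                if v is not None:
                    break
            if v is None:
                raise SimulationError(f"no genomic site realizes indel channel {chan}")
            finish(v.chrom, v.pos, v.ref, v.alt, ccf)

    # --- planted pathway SNVs ---
    gene_by_name = {g.name: g for g in genome.genes}
    for gene_name, event in truth.planted_pathway_hits:
        if event != "SNV_indel":
            continue
        g = gene_by_name[gene_name]
        for _ in range(1000):
            pos = int(rng.integers(g.start + 2, g.end - 2))
            ref_base = genome.base(g.chrom, pos)
            if ref_base in "ACGT":
                break
        alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
        finish(g.chrom, pos, ref_base, str(alt_base), 1.0, consequence="missense_variant")

    return variants, segments


def _default_id_exposures() -> dict[str, float]:
    return {"ID1": 0.3, "ID2": 0.3, "ID6": 0.2, "ID8": 0.1, "ID18": 0.1}


def plant_pathway_cn_events(
    truth: TruthRecord, genome: SyntheticGenome
) -> None:
    """Translate planted AMP/DEL/LOH pathway hits into CN events in place."""
    gene_by_name = {g.name: g for g in genome.genes}
    for gene_name, event in truth.planted_pathway_hits:
        if event == "SNV_indel":
            continue
        g = gene_by_name[gene_name]
        psi = truth.ploidy
        if event == "AMP":
            nmaj, nmin = int(np.ceil(2 * psi)), 1
        elif event == "DEL":
            total = int(np.floor(psi / 2))
            nmaj, nmin = max(total, 1), 0
            if nmaj > psi / 2:  # keep total <= psi/2 even at low ploidy
                nmaj, nmin = 1, 0
        elif event == "LOH":
            nmaj, nmin = max(int(round(psi)), 1), 0
        else:
            raise ValueError(f"unknown planted event {event!r}")
        truth.planted_cn_events.append((g.chrom, g.start, g.end, nmaj, nmin))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

#: per-stage mean clonal exposures; caricature of the disease landscape where
#: SBS17a/b dominate throughout, APOBEC (SBS2) and SBS41 emerge in primaries
#: and SBS17b rises further in metastases.
STAGE_EXPOSURES: dict[str, dict[str, float]] = {
    "barrett": {"SBS17a": 0.25, "SBS17b": 0.30, "SBS1": 0.20, "SBS5": 0.15, "SBS18": 0.10},
    "primary": {
        "SBS17a": 0.20,
        "SBS17b": 0.25,
        "SBS1": 0.10,
        "SBS5": 0.10,
        "SBS18": 0.10,
        "SBS2": 0.15,
        "SBS41": 0.10,
    },
    "metastasis": {"SBS17a": 0.20, "SBS17b": 0.40, "SBS1": 0.10, "SBS5": 0.10, "SBS18": 0.10, "SBS40": 0.10},
}

#: subclonal shift applied to the clonal exposures: SBS17a/b decrease, the
#: slack is redistributed to the ageing signatures.
SUBCLONAL_SBS17_SHIFT = -0.10


def subclonal_exposures(clonal: dict[str, float], shift: float = SUBCLONAL_SBS17_SHIFT) -> dict[str, float]:
    out = dict(clonal)
    moved = 0.0
    for sig in ("SBS17a", "SBS17b"):
        if sig in out:
            delta = min(out[sig], -shift if shift < 0 else 0.0)
            out[sig] -= delta
            moved += delta
    receivers = [s for s in ("SBS5", "SBS1", "SBS40") if s in out] or list(out)
    for s in receivers:
        out[s] += moved / len(receivers)
    total = sum(out.values())
    return {s: v / total for s, v in out.items()}


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_barrett: int = 10
    n_primary: int = 20
    n_metastasis: int = 5
    n_snvs: int = 5000
    n_indels: int = 300
    depth: int = 50
    purity_range: tuple[float, float] = (0.3, 0.9)
    subclone_prob: float = 0.5  # ~51% of samples carried subclonality
    subclone_ccf_range: tuple[float, float] = (0.3, 0.7)
    subclone_frac_range: tuple[float, float] = (0.25, 0.45)
    wgd_prob: float = 0.3
    genome_seed: int = 7
    n_chroms: int = 2
    chrom_length: int = 400_000
    periodic_signature: str | None = None  # e.g. "SBS17b"
    periodic_amplitude: float = 0.6

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
        for key in ("purity_range", "subclone_ccf_range", "subclone_frac_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def make_truth(config: CohortConfig, stage: str, sample_id: str, rng) -> TruthRecord:
    purity = float(rng.uniform(*config.purity_range))
    wgd = bool(rng.random() < config.wgd_prob) and stage != "barrett"
    ploidy = 4.0 if wgd else 2.0
    clonal = dict(STAGE_EXPOSURES[stage])
    exposures = {"clonal": clonal}
    clone_table: list[tuple[float, float]] = [(1.0, 1.0)]
    if rng.random() < config.subclone_prob:
        sub_ccf = float(rng.uniform(*config.subclone_ccf_range))
        sub_frac = float(rng.uniform(*config.subclone_frac_range))
        clone_table = [(1.0, 1.0 - sub_frac), (sub_ccf, sub_frac)]
        exposures["subclonal"] = subclonal_exposures(clonal)
    periodic = None
    if config.periodic_signature is not None:
        period = (
            SBS17B_HELICAL_PERIOD_BP
            if config.periodic_signature == "SBS17b"
            else BULK_HELICAL_PERIOD_BP
        )
        periodic = PeriodicConfig(config.periodic_signature, period, config.periodic_amplitude)
    return TruthRecord(
        sample_id=sample_id,
        stage=stage,
        purity=purity,
        ploidy=ploidy,
        wgd=wgd,
        exposures=exposures,
        id_exposures={"clonal": _default_id_exposures()},
        clone_table=clone_table,
        planted_period=periodic,
    )


def simulate_cohort(config: CohortConfig, out_dir: str | Path, seed: int = 0) -> pd.DataFrame:
    """Simulate a cohort into ``out_dir``; returns the truth table.

    Writes per sample a VCF and CN segment TSV, plus genome FASTA, dyad BED,
    purity table, clinical table, JSON truth and a checksum manifest.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    rng = np.random.default_rng(seed)
    genome = generate_genome(
        n_chroms=config.n_chroms,
        chrom_length=config.chrom_length,
        seed=config.genome_seed,
    )
    genome.write_fasta(out / "genome.fa")
    genome.write_dyads_bed(out / "dyads.bed")

    counts = [
        ("barrett", config.n_barrett),
        ("primary", config.n_primary),
        ("metastasis", config.n_metastasis),
    ]
    truths: list[TruthRecord] = []
    clinical_rows = []
    purities: dict[str, SamplePurityPloidy] = {}
    all_segs: list[CopyNumberSegment] = []
    i = 0
    for stage, n in counts:
        for _ in range(n):
            sid = f"S{i:03d}"
            truth = make_truth(config, stage, sid, rng)
            sample_seed = int(rng.integers(2**31 - 1))
            variants, segs = simulate_sample(
                genome,
                truth,
                n_snvs=config.n_snvs,
                n_indels=config.n_indels,
                depth=config.depth,
                seed=sample_seed,
            )
            write_vcf(variants, out / f"{sid}.vcf", genome.chrom_lengths, sample_id=sid)
            write_segments(segs, out / f"{sid}.segments.tsv")
            all_segs += segs
            purities[sid] = SamplePurityPloidy(sid, truth.purity, truth.ploidy)
            truths.append(truth)
            clinical_rows.append(
                {
                    "sample": sid,
                    "stage": stage,
                    "treated": bool(rng.random() < 0.5) and stage != "barrett",
                    "smoker": bool(rng.random() < 0.4),
                    "mandard_trg": int(rng.integers(1, 6)),
                    "os_months": round(float(rng.exponential(30.0)), 1),
                    "os_event": int(rng.random() < 0.6),
                }
            )
            i += 1

    clinical = pd.DataFrame(clinical_rows)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    write_purity_table(purities, out / "purity.tsv")
    truth_json = [_truth_to_json(t) for t in truths]
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1))

    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return pd.DataFrame(
        [
            {
                "sample": t.sample_id,
                "stage": t.stage,
                "purity": t.purity,
                "ploidy": t.ploidy,
                "wgd": t.wgd,
                "n_clones": len(t.clone_table),
                "subclonal_fraction": sum(f for c, f in t.clone_table if c < 1.0),
            }
            for t in truths
        ]
    ).set_index("sample")


def _truth_to_json(t: TruthRecord) -> dict:
    d = asdict(t)
    if t.planted_period is not None:
        d["planted_period"] = asdict(t.planted_period)
    return d
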