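"""Bundled synthetic signature reference matrices.

These are **synthetic stand-ins** for the COSMIC reference signatures, built
programmatically so the package ships no third-party data. Each profile
carries the name of the process it emulates (SBS17b, ID6, ...) because the
pipeline's rules — the 5% thresholding, the HR/colibactin/MMR deficiency
calls, SBS17 dominance grouping — are phrased in terms of those names. The
shapes are caricatures with the hallmark peaks of the real processes (e.g.
SBS17b concentrated on N[T>G]T, SBS1 on N[C>T]G) plus seeded Dirichlet
jitter, tuned to be mutually well separated so that refitting experiments
have an unambiguous ground truth. They are not the COSMIC profiles and must
not be used to analyse real genomes.

Indel profiles put their mass only on channels that are realizable on an
i.i.d. synthetic genome (short homopolymers/repeats, homology up to ~3 bp).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._channels import ID83_CHANNELS, SBS96_CHANNELS, SBS96_INDEX, ID83_INDEX
from .io import SignatureReference, make_signature_reference

#: nucleosome helical-repeat defaults used by the synthetic cohort generator:
#: bulk SNVs show a ~10.3 bp periodicity around the dyad, SBS17b-attributed
#: mutations a slightly shorter 10.15 bp repeat.
BULK_HELICAL_PERIOD_BP = 10.3
SBS17B_HELICAL_PERIOD_BP = 10.15

_JITTER_SEED = 20230715  # fixed: the reference is a deterministic artifact


def _sbs_profile(rng, peaks: dict[str, float], peak_mass: float, alpha: float = 0.6) -> np.ndarray:
    base = rng.dirichlet(np.full(96, alpha))
    prof = (1.0 - peak_mass) * base
    total = sum(peaks.values())
    for chan, w in peaks.items():
        prof[SBS96_INDEX[chan]] += peak_mass * w / total
    return prof / prof.sum()


def _chans(sub: str, five: str = "ACGT", three: str = "ACGT") -> list[str]:
    return [f"{f}[{sub}]{t}" for f in five for t in three]


def sbs_reference() -> SignatureReference:
    """Synthetic SBS-96 reference with the 12 processes the pipeline names."""
    rng = np.random.default_rng(_JITTER_SEED)
    cols: dict[str, np.ndarray] = {}
    # ageing: C>T at CpG
    cols["SBS1"] = _sbs_profile(rng, {c: 1.0 for c in _chans("C>T", three="G")}, 0.85)
    # APOBEC: C>T / C>G at TpC
    cols["SBS2"] = _sbs_profile(
        rng, {**{c: 1.0 for c in _chans("C>T", five="T")}, **{c: 0.5 for c in _chans("C>G", five="T")}}, 0.85
    )
    # HR deficiency: broad, flat-ish
    cols["SBS3"] = _sbs_profile(rng, {c: 1.0 for c in _chans("T>A")}, 0.35, alpha=4.0)
    # clock-like, flat with T>C tilt
    cols["SBS5"] = _sbs_profile(rng, {c: 1.0 for c in _chans("T>C", five="A")}, 0.45, alpha=4.0)
    cols["SBS8"] = _sbs_profile(rng, {c: 1.0 for c in _chans("C>A", five="C")}, 0.6)
    cols["SBS17a"] = _sbs_profile(rng, {c: 1.0 for c in _chans("T>C", three="T")}, 0.85)
    cols["SBS17b"] = _sbs_profile(
        rng, {"C[T>G]T": 3.0, "A[T>G]T": 1.5, "T[T>G]T": 1.0, "G[T>G]T": 0.5}, 0.9
    )
    # oxidative damage: C>A at NpCpA
    cols["SBS18"] = _sbs_profile(rng, {c: 1.0 for c in _chans("C>A", three="AT")}, 0.7)
    # platinum
    cols["SBS35"] = _sbs_profile(
        rng, {**{c: 1.0 for c in _chans("C>T", five="C")}, **{c: 0.7 for c in _chans("T>A", five="C")}}, 0.6
    )
    cols["SBS40"] = _sbs_profile(rng, {c: 1.0 for c in _chans("C>G")}, 0.35, alpha=4.0)
    # colibactin-like: T>N in A/T-rich context
    cols["SBS41"] = _sbs_profile(
        rng, {**{f"A[T>A]{t}": 1.0 for t in "AT"}, **{f"T[T>A]{t}": 1.0 for t in "AT"}}, 0.8
    )
    # MMR deficiency
    cols["SBS44"] = _sbs_profile(rng, {c: 1.0 for c in _chans("C>T", five="G", three="AC")}, 0.75)
    df = pd.DataFrame(cols, index=list(SBS96_CHANNELS))
    return make_signature_reference(df, "sbs96")


#: ID-83 channels realizable with useful frequency on a ~1 Mb i.i.d. genome
REALIZABLE_ID_CHANNELS: tuple[str, ...] = tuple(
    [f"1:Del:{b}:{i}" for b in "CT" for i in range(6)]
    + [f"1:Ins:{b}:{i}" for b in "CT" for i in range(6)]
    + [f"2:Del:R:{i}" for i in range(3)]
    + ["3:Del:R:0", "3:Del:R:1", "4:Del:R:0", "5:Del:R:0"]
    + [f"2:Ins:R:{i}" for i in range(3)]
    + ["3:Ins:R:0", "3:Ins:R:1", "4:Ins:R:0", "4:Ins:R:1", "5:Ins:R:0", "5:Ins:R:1"]
    + ["2:Del:M:1", "3:Del:M:1", "3:Del:M:2", "4:Del:M:1", "4:Del:M:2", "5:Del:M:1", "5:Del:M:2"]
)


def _id_profile(rng, peaks: dict[str, float], peak_mass: float) -> np.ndarray:
    prof = np.zeros(83)
    base = rng.dirichlet(np.full(len(REALIZABLE_ID_CHANNELS), 0.5))
    for chan, w in zip(REALIZABLE_ID_CHANNELS, base):
        prof[ID83_INDEX[chan]] = (1.0 - peak_mass) * w
    total = sum(peaks.values())
    for chan, w in peaks.items():
        prof[ID83_INDEX[chan]] += peak_mass * w / total
    return prof / prof.sum()


def id_reference() -> SignatureReference:
    """Synthetic ID-83 reference (ID1, ID2, ID6, ID8, ID18 stand-ins)."""
    rng = np.random.default_rng(_JITTER_SEED + 1)
    cols: dict[str, np.ndarray] = {}
    # replication slippage: 1 bp T insertions at long homopolymers
    cols["ID1"] = _id_profile(rng, {"1:Ins:T:4": 1.0, "1:Ins:T:5": 1.0}, 0.85)
    # slippage deletions at long T homopolymers
    cols["ID2"] = _id_profile(rng, {"1:Del:T:3": 0.6, "1:Del:T:4": 1.0, "1:Del:T:5": 1.0}, 0.85)
    # HR deficiency: microhomology-flanked deletions
    cols["ID6"] = _id_profile(
        rng, {"5:Del:M:1": 1.0, "5:Del:M:2": 0.8, "4:Del:M:1": 0.6, "3:Del:M:1": 0.4}, 0.85
    )
    # NHEJ: blunt >=4 bp deletions without repeat or homology
    cols["ID8"] = _id_profile(rng, {"5:Del:R:0": 1.0, "4:Del:R:0": 0.7}, 0.85)
    # colibactin: single T deletions at short runs
    cols["ID18"] = _id_profile(rng, {"1:Del:T:1": 1.0, "1:Del:T:2": 0.8, "2:Del:R:0": 0.4}, 0.85)
    df = pd.DataFrame(cols, index=list(ID83_CHANNELS))
    return make_signature_reference(df, "id83")


def signature_reference(kind: str = "sbs96") -> SignatureReference:
    """The bundled synthetic reference of the requested kind."""
    if kind == "sbs96":
        return sbs_reference()
    if kind == "id83":
        return id_reference()
    raise ValueError(f"unknown reference kind {kind!r}")
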