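"""Convenience orchestration: clonality-resolved signature exposures.

Splits each sample's SNVs into compartments using the clonality/timing
decomposition, builds per-compartment catalogues and refits signatures on
each, yielding the inputs for subclonal-shift analysis and
compartment-resolved stage classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalogue import build_catalogue
from .clonality import ClonalityResult, decompose_sample
from .fitting import fit_cohort
from .genome import SyntheticGenome
from .io import CopyNumberSegment, SignatureReference, SomaticVariant

CLONAL_LABELS = ("clonal_early", "clonal_late", "clonal_other")


@dataclass
class SampleDecomposition:
    sample_id: str
    clonality: ClonalityResult
    variants: list[SomaticVariant]


def decompose_cohort(
    variants_by_sample: dict[str, list[SomaticVariant]],
    segments_by_sample: dict[str, list[CopyNumberSegment]],
    purity_by_sample: dict[str, float],
    ploidy_by_sample: dict[str, float],
    n_ref: int = 500,
    seed: int = 0,
) -> dict[str, SampleDecomposition]:
    out = {}
    for sid, variants in variants_by_sample.items():
        snvs = [v for v in variants if v.kind == "snv"]
        res = decompose_sample(
            snvs,
            segments_by_sample[sid],
            purity_by_sample[sid],
            ploidy_by_sample[sid],
            sample_id=sid,
            n_ref=n_ref,
            seed=seed,
        )
        out[sid] = SampleDecomposition(sid, res, snvs)
    return out


def clonality_summary(decompositions: dict[str, SampleDecomposition]) -> pd.DataFrame:
    """Per-sample clonality/timing summary (fractions of labelled SNVs)."""
    rows = []
    for sid, dec in decompositions.items():
        counts = dec.clonality.label_counts()
        total = counts.sum()
        early = counts.get("clonal_early", 0)
        late = counts.get("clonal_late", 0)
        rows.append(
            {
                "sample": sid,
                "dip_p": dec.clonality.dip_p,
                "is_multimodal": dec.clonality.is_multimodal,
                "subclonal_fraction": counts.get("subclonal", 0) / total if total else 0.0,
                "early_fraction": early / (early + late) if early + late else 0.0,
                "wgd": dec.clonality.wgd.wgd,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def compartment_catalogues(
    decompositions: dict[str, SampleDecomposition],
    genome: SyntheticGenome,
    compartments: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, pd.DataFrame]:
    """SBS-96 catalogues per compartment (clonal vs subclonal by default)."""
    if compartments is None:
        compartments = {"clonal": CLONAL_LABELS, "subclonal": ("subclonal",)}
    out = {}
    for comp, labels in compartments.items():
        variants_by_sample = {}
        for sid, dec in decompositions.items():
            mask = dec.clonality.assignments["label"].isin(labels).to_numpy()
            variants_by_sample[sid] = [v for v, keep in zip(dec.variants, mask) if keep]
        cat, _ = build_catalogue(variants_by_sample, genome, "sbs96")
        out[comp] = cat
    return out


def compartment_exposures(
    compartment_cats: dict[str, pd.DataFrame],
    reference: SignatureReference,
    threshold: float = 0.05,
    min_mutations: int = 50,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.Series]]:
    """Refit exposures per compartment; samples below the mutation floor are
    dropped from that compartment's table. Returns (fractions, counts)."""
    fractions, counts = {}, {}
    for comp, cat in compartment_cats.items():
        n = cat.sum(axis=1)
        keep = n >= min_mutations
        table = fit_cohort(cat.loc[keep], reference, threshold, compartment=comp)
        fractions[comp] = table.fractions
        counts[comp] = n
    return fractions, counts
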