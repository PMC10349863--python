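"""Cohort-level signature dynamics.

Subclonal shifts compare each sample's subclonal against clonal exposures
(Delta = subclonal - clonal, in fractions); a sample contributes only when
both compartments carry enough mutations for a stable refit. Group
comparisons use two-sided Wilcoxon tests (rank-sum unpaired, signed-rank
paired) with optional Benjamini-Hochberg correction; dominance grouping
labels samples where a signature set contributes the strict majority of
mutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_COMPARTMENT_MUTATIONS = 50


@dataclass
class ShiftTable:
    """Per sample x signature exposure shift between compartments."""

    deltas: pd.DataFrame  # samples x signatures; NaN where a compartment was too small
    stage: pd.Series | None = None

    def stage_summary(self) -> pd.DataFrame:
        """Median and IQR of each signature's shift per stage."""
        if self.stage is None:
            raise ValueError("no stage labels attached")
        rows = []
        for stage, grp in self.deltas.groupby(self.stage):
            med = grp.median()
            q1, q3 = grp.quantile(0.25), grp.quantile(0.75)
            for sig in self.deltas.columns:
                rows.append((stage, sig, med[sig], q1[sig], q3[sig]))
        return pd.DataFrame(rows, columns=["stage", "signature", "median", "q1", "q3"])


def subclonal_shifts(
    clonal: pd.DataFrame,
    subclonal: pd.DataFrame,
    clonal_counts: pd.Series | None = None,
    subclonal_counts: pd.Series | None = None,
    min_mutations: int = MIN_COMPARTMENT_MUTATIONS,
    stage: pd.Series | None = None,
) -> ShiftTable:
    """Delta = subclonal - clonal exposure fractions per sample/signature.

    Only samples present in both tables contribute; samples whose
    compartment mutation count is below ``min_mutations`` are masked NaN.
    """
    samples = clonal.index.intersection(subclonal.index)
    sigs = clonal.columns.intersection(subclonal.columns)
    deltas = subclonal.loc[samples, sigs] - clonal.loc[samples, sigs]
    for counts in (clonal_counts, subclonal_counts):
        if counts is not None:
            small = counts.reindex(samples).fillna(0) < min_mutations
            deltas.loc[small[small].index] = np.nan
    return ShiftTable(deltas, stage.reindex(samples) if stage is not None else None)


def compare_groups(
    values_by_group: dict[str, np.ndarray | list[float]],
    paired: bool = False,
    adjust: str = "none",
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon comparisons between groups.

    Unpaired comparisons use the rank-sum (Mann-Whitney) test with the
    exact null distribution when there are no ties and groups are small;
    paired comparisons use the signed-rank test on the pairwise
    differences. ``adjust="BH"`` adds Benjamini-Hochberg q-values across
    the tested family. All-tied comparisons report p = 1 with a flag.
    """
    if adjust not in ("none", "BH"):
        raise ValueError("adjust must be 'none' or 'BH'")
    names = list(values_by_group)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            x = np.asarray(values_by_group[a], dtype=float)
            y = np.asarray(values_by_group[b], dtype=float)
            if paired:
                if len(x) != len(y) or len(x) < 3:
                    raise ValueError("paired comparison needs >= 3 pairs of equal length")
                diffs = x - y
                if np.all(diffs == 0):
                    rows.append((a, b, 0.0, 1.0, "all-tied"))
                    continue
                res = stats.wilcoxon(x, y, alternative="two-sided")
                rows.append((a, b, float(res.statistic), float(res.pvalue), ""))
            else:
                if len(x) < 3 or len(y) < 3:
                    raise ValueError("unpaired comparison needs >= 3 values per group")
                if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                    rows.append((a, b, len(x) * len(y) / 2.0, 1.0, "all-tied"))
                    continue
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                rows.append((a, b, float(res.statistic), float(res.pvalue), ""))
    out = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p", "flag"])
    if adjust == "BH" and len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def dominance_groups(exposures: pd.DataFrame, signatures: set[str] | list[str]) -> pd.Series:
    """"dominant" when the signature set contributes a strict majority.

    Mirrors the SBS17 dominance grouping: samples where the named
    signatures together exceed 50% of the (normalized) exposure.
    """
    sigs = [s for s in signatures if s in exposures.columns]
    total = exposures[sigs].sum(axis=1) if sigs else pd.Series(0.0, index=exposures.index)
    return pd.Series(
        np.where(total > 0.5, "dominant", "other"), index=exposures.index, name="dominance"
    )


COMPARTMENTS = ("clonal_early", "clonal_late", "subclonal")


def build_stage_features(
    exposures: pd.DataFrame,
    clonality_summary: pd.DataFrame | None = None,
    compartment_exposures: dict[str, pd.DataFrame] | None = None,
    mode: str = "overall",
) -> pd.DataFrame:
    """Feature matrix for stage classification.

    ``overall``: one column per signature plus ``subclonal_fraction`` and
    ``early_fraction`` from the clonality summary. ``compartment_split``:
    one column per (signature x compartment); a sample missing a
    compartment gets zeros plus a missingness indicator column.
    """
    if mode == "overall":
        out = exposures.copy()
        if clonality_summary is not None:
            out["subclonal_fraction"] = clonality_summary.reindex(out.index)[
                "subclonal_fraction"
            ].fillna(0.0)
            out["early_fraction"] = clonality_summary.reindex(out.index)[
                "early_fraction"
            ].fillna(0.0)
        return out
    if mode != "compartment_split":
        raise ValueError("mode must be 'overall' or 'compartment_split'")
    if compartment_exposures is None:
        raise ValueError("compartment_split mode requires compartment exposures")
    blocks = []
    for comp in COMPARTMENTS:
        table = compartment_exposures.get(comp)
        if table is None:
            table = pd.DataFrame(0.0, index=exposures.index, columns=exposures.columns)
            missing = pd.Series(1.0, index=exposures.index)
        else:
            missing = (~exposures.index.isin(table.index)).astype(float)
            table = table.reindex(exposures.index).fillna(0.0)
        table = table.add_prefix(f"{comp}:")
        table[f"{comp}:missing"] = np.asarray(missing, dtype=float)
        blocks.append(table)
    out = pd.concat(blocks, axis=1)
    # drop indicator columns that are constant zero (compartment present everywhere)
    for comp in COMPARTMENTS:
        col = f"{comp}:missing"
        if (out[col] == 0).all():
            out = out.drop(columns=col)
    return out
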