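"""DDR gene/pathway alteration calls, chromosomal instability and
proliferation scores.

Copy-number classes follow ploidy-relative rules: a gene is amplified when
its covering segment's total copy number is at least twice the sample
ploidy, deleted when at most half of it, and under LOH when the minor
allele is completely lost. SNV/indel hits require a consequence from a
configurable allow-list (the non-synonymous categories annotated
upstream). Chromosomal instability counts segments with abnormal total
copy number (relative to the rounded ploidy) spanning more than 5% of
their chromosome, Z-scored across the cohort. The proliferation score is
1 - QS, QS being the mean cohort Z-score of G0-arrest marker genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GeneInterval
from .io import CopyNumberSegment, SomaticVariant

EVENT_CLASSES = ("SNV_indel", "AMP", "DEL", "LOH")

#: non-synonymous consequence categories counted as gene hits
DEFAULT_CONSEQUENCES = (
    "missense_variant",
    "stop_gained",
    "stop_lost",
    "frameshift_variant",
    "inframe_insertion",
    "inframe_deletion",
    "initiator_codon_variant",
    "incomplete_terminal_codon_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "TF_binding_site_variant",
)


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneCnCall:
    amp: bool
    dele: bool
    loh: bool
    flag: str = ""


def classify_gene_cn(
    gene: GeneInterval, segments: list[CopyNumberSegment], ploidy: float
) -> GeneCnCall:
    """AMP/DEL/LOH from the segment with maximal overlap of the gene."""
    best, best_ov = None, 0
    for s in segments:
        if s.chrom != gene.chrom:
            continue
        ov = min(s.end, gene.end) - max(s.start, gene.start)
        if ov > best_ov:
            best, best_ov = s, ov
    if best is None:
        return GeneCnCall(False, False, False, flag="no-CN")
    total = best.total
    return GeneCnCall(
        amp=total >= 2.0 * ploidy,
        dele=total <= ploidy / 2.0,
        loh=best.n_minor == 0,
    )


def classify_gene_snv(
    variants: list[SomaticVariant],
    gene: GeneInterval,
    consequence_allowlist: tuple[str, ...] | None = DEFAULT_CONSEQUENCES,
) -> bool:
    """True when a qualifying variant overlaps the gene.

    With ``consequence_allowlist=None`` any overlapping variant counts;
    otherwise variants must carry a consequence (a missing annotation on an
    overlapping variant is a configuration error).
    """
    for v in variants:
        if v.chrom != gene.chrom or not gene.start <= v.pos < gene.end:
            continue
        if consequence_allowlist is None:
            return True
        if v.consequence is None:
            raise ConfigurationError(
                f"variant {v.chrom}:{v.pos} lacks a consequence annotation; "
                "pass consequence_allowlist=None to count any overlapping variant"
            )
        if v.consequence in consequence_allowlist:
            return True
    return False


# ---------------------------------------------------------------------------
# pathway matrix
# ---------------------------------------------------------------------------

@dataclass
class AlterationMatrix:
    """samples x units boolean matrices, one per event class."""

    matrices: dict[str, pd.DataFrame]  # class -> samples x pathways

    def fractions(self) -> pd.DataFrame:
        """Pathway x class fraction of altered samples, ordered by
        decreasing deletion fraction."""
        frac = pd.DataFrame({cls: m.mean(axis=0) for cls, m in self.matrices.items()})
        return frac.sort_values("DEL", ascending=False)


def gene_alteration_calls(
    variants_by_sample: dict[str, list[SomaticVariant]],
    segments_by_sample: dict[str, list[CopyNumberSegment]],
    ploidy_by_sample: dict[str, float],
    genes: list[GeneInterval],
    consequence_allowlist: tuple[str, ...] | None = DEFAULT_CONSEQUENCES,
) -> dict[str, pd.DataFrame]:
    """Per-class samples x genes boolean call matrices."""
    samples = list(variants_by_sample)
    gene_names = [g.name for g in genes]
    out = {cls: pd.DataFrame(False, index=samples, columns=gene_names) for cls in EVENT_CLASSES}
    for sid in samples:
        segs = segments_by_sample.get(sid, [])
        ploidy = ploidy_by_sample[sid]
        variants = variants_by_sample[sid]
        annotated = [v for v in variants if v.consequence is not None]
        for g in genes:
            cn = classify_gene_cn(g, segs, ploidy)
            out["AMP"].loc[sid, g.name] = cn.amp
            out["DEL"].loc[sid, g.name] = cn.dele
            out["LOH"].loc[sid, g.name] = cn.loh
            out["SNV_indel"].loc[sid, g.name] = classify_gene_snv(
                annotated, g, consequence_allowlist
            )
    return out


def pathway_matrix(
    gene_calls: dict[str, pd.DataFrame],
    membership: pd.DataFrame,
) -> AlterationMatrix:
    """Aggregate gene calls to pathways (a pathway is hit when any member is).

    ``membership`` needs columns ``gene`` and ``pathway``. Genes in the
    calls but absent from the membership table are ignored.
    """
    if not {"gene", "pathway"} <= set(membership.columns):
        raise ConfigurationError("membership table needs 'gene' and 'pathway' columns")
    pathways = sorted(membership["pathway"].unique())
    members = {
        pw: [g for g in grp["gene"] if g in next(iter(gene_calls.values())).columns]
        for pw, grp in membership.groupby("pathway")
    }
    matrices = {}
    for cls, calls in gene_calls.items():
        m = pd.DataFrame(False, index=calls.index, columns=pathways)
        for pw in pathways:
            if members[pw]:
                m[pw] = calls[members[pw]].any(axis=1)
        matrices[cls] = m
    return AlterationMatrix(matrices)


# ---------------------------------------------------------------------------
# CIN / proliferation
# ---------------------------------------------------------------------------

@dataclass
class CinScore:
    raw: pd.Series  # per-sample count of qualifying segments
    z: pd.Series  # cohort Z-score


def cin_score(
    segments_by_sample: dict[str, list[CopyNumberSegment]],
    ploidy_by_sample: dict[str, float],
    chrom_lengths: dict[str, int],
) -> CinScore:
    """Count of abnormal-CN segments spanning > 5% of their chromosome.

    A segment is abnormal when its total copy number differs from the
    sample's rounded ploidy. Z-scores are taken across the cohort (0 for a
    zero-variance cohort).
    """
    raw = {}
    for sid, segs in segments_by_sample.items():
        base = round(ploidy_by_sample[sid])
        count = 0
        for s in segs:
            if s.total == base:
                continue
            if (s.end - s.start) > 0.05 * chrom_lengths[s.chrom]:
                count += 1
        raw[sid] = count
    raw_s = pd.Series(raw, name="cin_raw")
    sd = raw_s.std(ddof=0)
    z = (raw_s - raw_s.mean()) / sd if sd > 0 else raw_s * 0.0
    return CinScore(raw_s, z.rename("cin_z"))


def proliferation_score(
    expression: pd.DataFrame, g0_markers: list[str]
) -> pd.Series:
    """1 - QS, QS = mean cohort Z-score of G0-arrest markers.

    ``expression`` is samples x genes. Missing markers are dropped with a
    warning counter; all markers missing is an error.
    """
    if len(expression) < 2:
        raise ConfigurationError("proliferation score needs >= 2 samples")
    present = [g for g in g0_markers if g in expression.columns]
    if not present:
        raise ConfigurationError("none of the G0 marker genes are in the expression matrix")
    sub = expression[present].astype(float)
    sd = sub.std(ddof=0)
    sd = sd.replace(0.0, np.nan)
    z = (sub - sub.mean()) / sd
    qs = z.mean(axis=1).fillna(0.0)
    return (1.0 - qs).rename("proliferation")
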