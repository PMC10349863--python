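"""Transcription and replication strand assignment and bias statistics.

An SNV is reported in its pyrimidine-centred representation; strand labels
therefore describe where the mutated *pyrimidine* sits. For transcription:
the mutation is on the transcribed (template) strand when the pyrimidine
strand is opposite the gene's coding strand. For replication, the fixed
documented convention is: in a domain whose fork travels rightwards, the
"+" strand is replicated as the lagging-strand template, so a pyrimidine
on "+" is labelled lagging; in a left-travelling domain the roles swap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .catalogue import ContextualizedSNV
from .genome import GeneInterval, ReplicationDomain


def assign_tx_strand(snv: ContextualizedSNV, genes: list[GeneInterval]) -> str:
    """{transcribed, untranscribed, intergenic, ambiguous} for one SNV."""
    chrom, pos = snv.variant.chrom, snv.variant.pos
    strands = {g.strand for g in genes if g.chrom == chrom and g.start <= pos < g.end}
    if not strands:
        return "intergenic"
    if len(strands) > 1:
        return "ambiguous"
    gene_strand = strands.pop()
    return "transcribed" if snv.pyrimidine_strand != gene_strand else "untranscribed"


def assign_repl_strand(snv: ContextualizedSNV, domains: list[ReplicationDomain]) -> str:
    """{leading, lagging, unknown} under the documented convention."""
    chrom, pos = snv.variant.chrom, snv.variant.pos
    hits = [d for d in domains if d.chrom == chrom and d.start <= pos < d.end]
    if len(hits) != 1:
        return "unknown"
    right = hits[0].direction == "right"
    pyr_plus = snv.pyrimidine_strand == "+"
    return "lagging" if (right == pyr_plus) else "leading"


@dataclass
class StrandBias:
    n_strand1: int
    n_strand2: int
    log2_ratio: float
    p_value: float


def strand_bias(n_strand1: int, n_strand2: int) -> StrandBias:
    """log2 count ratio and two-sided binomial test against 0.5.

    A zero count on either strand gets a +0.5 continuity correction in the
    ratio (the test uses the raw counts).
    """
    a, b = n_strand1, n_strand2
    if a == 0 or b == 0:
        ratio = float(np.log2((a + 0.5) / (b + 0.5)))
    else:
        ratio = float(np.log2(a / b))
    if a + b == 0:
        return StrandBias(a, b, 0.0, 1.0)
    p = binomtest(a, a + b, 0.5, alternative="two-sided").pvalue
    return StrandBias(a, b, ratio, float(p))


def strand_bias_table(labels: list[str], pair: tuple[str, str]) -> StrandBias:
    """Bias between two label classes (e.g. ("lagging", "leading"))."""
    n1 = sum(1 for s in labels if s == pair[0])
    n2 = sum(1 for s in labels if s == pair[1])
    return strand_bias(n1, n2)
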