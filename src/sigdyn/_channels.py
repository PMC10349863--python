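"""Canonical mutation channel sets (SBS-96, ID-83) and sequence helpers.

Channel labels follow the COSMIC conventions used throughout the signature
literature: single base substitutions are pyrimidine-centred trinucleotide
channels such as ``A[C>T]G``; indels use the 83-channel scheme of 1-bp
homopolymer events, longer repeat-mediated events and microhomology-flanked
deletions, with labels such as ``1:Del:T:4`` or ``5:Del:M:2``.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: 96 pyrimidine-centred trinucleotide channels, grouped by substitution class
#: (C>A, C>G, C>T, T>A, T>C, T>G) with 5' and 3' flanks cycling A,C,G,T.
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)


def _id83_channels() -> tuple[str, ...]:
    chans: list[str] = []
    for base in ("C", "T"):  # 1-bp deletions: run length 1..6+ encoded 0..5
        chans += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):  # 1-bp insertions: adjacent run length 0..5+
        chans += [f"1:Ins:{base}:{i}" for i in range(6)]
    for size in (2, 3, 4, 5):  # >=2bp deletions at repeats: copies 1..6+ -> 0..5
        chans += [f"{size}:Del:R:{i}" for i in range(6)]
    for size in (2, 3, 4, 5):  # >=2bp insertions at repeats: copies 0..5+
        chans += [f"{size}:Ins:R:{i}" for i in range(6)]
    for size, max_h in ((2, 1), (3, 2), (4, 3), (5, 5)):  # microhomology dels
        chans += [f"{size}:Del:M:{h}" for h in range(1, max_h + 1)]
    return tuple(chans)


ID83_CHANNELS: tuple[str, ...] = _id83_channels()
assert len(SBS96_CHANNELS) == 96
assert len(ID83_CHANNELS) == 83

SBS96_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}
ID83_INDEX = {c: i for i, c in enumerate(ID83_CHANNELS)}

#: the 32 pyrimidine-centred trinucleotide contexts, in SBS96 flank order
PYRIMIDINE_TRINUCS: tuple[str, ...] = tuple(
    f"{five}{centre}{three}"
    for centre in "CT"
    for five in "ACGT"
    for three in "ACGT"
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def fold_pyrimidine(seq: str) -> str:
    """Orient a context so its middle base is a pyrimidine.

    ``seq`` must have odd length; returns ``seq`` unchanged if the centre is
    C/T, the reverse complement if it is A/G.
    """
    mid = seq[len(seq) // 2]
    if mid in "CT":
        return seq
    return revcomp(seq)


def sbs_channel(trinuc: str, ref: str, alt: str) -> tuple[str, str]:
    """Build the pyrimidine-centred SBS-96 channel for a substitution.

    Parameters
    ----------
    trinuc : reference trinucleotide around the mutated base (genome strand).
    ref, alt : reference and alternate base on the genome strand.

    Returns
    -------
    (channel, pyrimidine_strand) where ``pyrimidine_strand`` is ``"+"`` when
    the mutated pyrimidine lies on the reported genome strand and ``"-"``
    when the representation was reverse-complemented.
    """
    if len(trinuc) != 3 or trinuc[1] != ref:
        raise ValueError(f"trinucleotide {trinuc!r} does not centre on ref {ref!r}")
    if ref in "CT":
        return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}", "+"
    rc = revcomp(trinuc)
    return f"{rc[0]}[{revcomp(ref)}>{revcomp(alt)}]{rc[2]}", "-"
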