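"""Mutation clonality and timing from VAFs, purity and allele-specific CN.

Each mutation's cancer cell fraction (CCF) and multiplicity follow the
standard relation: with purity rho and local copy number (n_major, n_minor),
the locus-level expected VAF of a mutation on m copies in a fraction c of
tumour cells is rho*m*c / (rho*(n_major+n_minor) + (1-rho)*2). Inverting,
m = clamp(round(vaf*N/rho), 1, n_major) and ccf = vaf*N/(rho*m).

Sample-level subclonality is assessed with Hartigan's dip test on the CCF
distribution (Monte Carlo p-value); multimodal samples are decomposed with
a two-component Gaussian mixture whose lower-CCF component defines the
subclonal population. Clonal mutations are timed relative to copy gains in
a whole-genome-doubling-aware way: in segments with n_major >= 2 a
multiplicity >= 2 mutation predates the gain (clonal_early), multiplicity 1
postdates it (clonal_late); without a gain the timing is uninformative
(clonal_other).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from ._dip import dip_statistic
from .genome import ArgumentError
from .io import CopyNumberSegment, SomaticVariant

CCF_CAP = 1.25
MIN_DIP_VALUES = 10
DIP_ALPHA = 0.05


@dataclass
class WgdStatus:
    sample_id: str
    wgd: bool
    fraction_genome_major_ge2: float
    ploidy: float


def ccf_and_multiplicity(
    vaf: float, n_major: int, n_minor: int, purity: float
) -> tuple[float, int, bool]:
    """(ccf, multiplicity, overflow_flag) for one mutation.

    CCF is capped at 1.25; the flag records that the cap was applied.
    """
    if not 0.0 < purity <= 1.0:
        raise ArgumentError("purity must lie in (0, 1]")
    if n_major + n_minor < 1:
        raise ArgumentError("total copy number must be >= 1")
    N = purity * (n_major + n_minor) + (1.0 - purity) * 2.0
    m = int(np.clip(round(vaf * N / purity), 1, max(n_major, 1)))
    ccf = vaf * N / (purity * m)
    if ccf > CCF_CAP:
        return CCF_CAP, m, True
    return ccf, m, False


# ---------------------------------------------------------------------------
# dip test
# ---------------------------------------------------------------------------

_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _null_dips(n: int, n_ref: int, seed: int) -> np.ndarray:
    key = (n, n_ref, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.array(
            [dip_statistic(rng.uniform(0.0, 1.0, n)) for _ in range(n_ref)]
        )
    return _NULL_CACHE[key]


def dip_test(values, n_ref: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Hartigan's dip test; Monte Carlo p against uniform samples of equal n.

    p = (1 + #{null dip >= observed}) / (1 + n_ref).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < MIN_DIP_VALUES:
        raise ArgumentError(f"dip test needs >= {MIN_DIP_VALUES} values")
    stat = dip_statistic(values)
    null = _null_dips(len(values), n_ref, seed)
    p = (1 + int(np.sum(null >= stat))) / (1 + n_ref)
    return stat, p


# ---------------------------------------------------------------------------
# subclonal mixture
# ---------------------------------------------------------------------------

class SubclonalMixture(BaseEstimator):
    """Two-component 1-D Gaussian mixture separating clonal from subclonal.

    Initialized from a median split of the CCFs; EM with tolerance 1e-6,
    up to 500 iterations and a 1e-4 variance floor. The component with mean
    nearer 1 is the clonal population. The fit is ``degenerate_`` (sample
    effectively fully clonal) when a component weight falls below 1%, the
    component means are indistinguishable, or the putative subclonal mean
    exceeds ``max_subclonal_mean``: integer multiplicity assignment in
    high-copy segments produces artifact CCF modes hugging 1 that would
    otherwise masquerade as subclones.

    Attributes: ``means_``, ``sds_``, ``weights_`` (clonal first),
    ``subclonal_fraction_``, ``degenerate_``.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500, var_floor: float = 1e-4,
                 min_weight: float = 0.01, posterior_cutoff: float = 0.5,
                 max_subclonal_mean: float = 0.8):
        self.tol = tol
        self.max_iter = max_iter
        self.var_floor = var_floor
        self.min_weight = min_weight
        self.posterior_cutoff = posterior_cutoff
        self.max_subclonal_mean = max_subclonal_mean

    def fit(self, X, y=None) -> "SubclonalMixture":
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        lo, hi = x[x[:, 0] <= np.median(x)], x[x[:, 0] > np.median(x)]
        means_init = np.array([[lo.mean() if len(lo) else x.mean()],
                               [hi.mean() if len(hi) else x.mean()]])
        gm = GaussianMixture(
            n_components=2,
            covariance_type="diag",
            tol=self.tol,
            max_iter=self.max_iter,
            reg_covar=self.var_floor,
            means_init=means_init,
            weights_init=np.array([0.5, 0.5]),
            random_state=0,
        ).fit(x)
        means = gm.means_[:, 0]
        order = np.argsort(np.abs(means - 1.0))  # clonal component (nearer 1) first
        self._gm = gm
        self._order = order
        self.means_ = means[order]
        self.sds_ = np.sqrt(gm.covariances_[:, 0])[order]
        self.weights_ = gm.weights_[order]
        self.subclonal_fraction_ = float(self.weights_[1])
        self.degenerate_ = bool(
            self.weights_.min() < self.min_weight
            or abs(self.means_[0] - self.means_[1]) < 1e-3
            or self.means_[1] > self.max_subclonal_mean
        )
        return self

    def predict_subclonal(self, X) -> np.ndarray:
        """Boolean mask: posterior of the subclonal component > cutoff.

        Ties and degenerate fits resolve to clonal.
        """
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        if self.degenerate_:
            return np.zeros(len(x), dtype=bool)
        post = self._gm.predict_proba(x)[:, self._order]
        return post[:, 1] > self.posterior_cutoff


def fit_subclonal_mixture(ccfs) -> SubclonalMixture:
    """Fit the two-component CCF mixture (convenience wrapper)."""
    return SubclonalMixture().fit(ccfs)


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

def wgd_status(
    segments: list[CopyNumberSegment], ploidy: float, sample_id: str = ""
) -> WgdStatus:
    """Whole-genome doubling: > 50% of the genome at n_major >= 2 and ploidy > 2.9."""
    total = sum(s.end - s.start for s in segments)
    ge2 = sum(s.end - s.start for s in segments if s.n_major >= 2)
    frac = ge2 / total if total else 0.0
    return WgdStatus(sample_id, bool(frac > 0.5 and ploidy > 2.9), frac, ploidy)


def timing_label(is_subclonal: bool, multiplicity: int, n_major: int | None) -> str:
    if is_subclonal:
        return "subclonal"
    if n_major is None:
        return "clonal_other"
    if n_major >= 2:
        return "clonal_early" if multiplicity >= 2 else "clonal_late"
    return "clonal_other"


# ---------------------------------------------------------------------------
# per-sample decomposition
# ---------------------------------------------------------------------------

@dataclass
class ClonalityResult:
    """Per-mutation assignments plus sample-level summary."""

    assignments: pd.DataFrame  # chrom,pos,ref,alt,vaf,ccf,multiplicity,n_major,n_minor,label,flag
    dip_stat: float
    dip_p: float
    is_multimodal: bool
    subclonal_fraction: float
    mixture: SubclonalMixture | None
    wgd: WgdStatus
    flags: list[str]

    def label_counts(self) -> pd.Series:
        return self.assignments["label"].value_counts()


def decompose_sample(
    variants: list[SomaticVariant],
    segments: list[CopyNumberSegment],
    purity: float,
    ploidy: float,
    sample_id: str = "",
    n_ref: int = 2000,
    seed: int = 0,
    dip_alpha: float = DIP_ALPHA,
) -> ClonalityResult:
    """Full clonality/timing decomposition of one sample.

    Mutations without a covering CN segment are labelled ``clonal_other``
    with a ``no-CN`` flag and excluded from the dip test and timing.
    """
    from .simulate import _SegmentLookup  # shared interval lookup

    lookup = _SegmentLookup(segments)
    rows = []
    for v in variants:
        seg = lookup.find(v.chrom, v.pos)
        if seg is None:
            rows.append((v.chrom, v.pos, v.ref, v.alt, v.vaf, np.nan, 0, -1, -1, "no-CN"))
            continue
        ccf, m, overflow = ccf_and_multiplicity(v.vaf, seg.n_major, seg.n_minor, purity)
        rows.append(
            (v.chrom, v.pos, v.ref, v.alt, v.vaf, ccf, m, seg.n_major, seg.n_minor,
             "ccf-capped" if overflow else "")
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "vaf", "ccf", "multiplicity",
                 "n_major", "n_minor", "flag"],
    )
    flags: list[str] = []
    has_cn = df["flag"] != "no-CN"
    ccfs = df.loc[has_cn, "ccf"].to_numpy()

    mixture: SubclonalMixture | None = None
    is_multimodal = False
    subclonal_fraction = 0.0
    if len(ccfs) < MIN_DIP_VALUES:
        dip_stat_, dip_p = float("nan"), 1.0
        flags.append("insufficient-n")
    else:
        dip_stat_, dip_p = dip_test(ccfs, n_ref=n_ref, seed=seed)
        if dip_p < dip_alpha:
            mixture = fit_subclonal_mixture(ccfs)
            if mixture.degenerate_:
                flags.append("degenerate-mixture")
                mixture = None
            else:
                is_multimodal = True
                subclonal_fraction = mixture.subclonal_fraction_

    sub_mask = np.zeros(len(df), dtype=bool)
    if mixture is not None:
        sub_mask[np.flatnonzero(has_cn)] = mixture.predict_subclonal(ccfs)

    wgd = wgd_status(segments, ploidy, sample_id)
    labels = [
        "clonal_other" if not cn else timing_label(sub, m, nmaj)
        for cn, sub, m, nmaj in zip(has_cn, sub_mask, df["multiplicity"], df["n_major"])
    ]
    df["label"] = labels
    return ClonalityResult(
        assignments=df,
        dip_stat=dip_stat_,
        dip_p=dip_p,
        is_multimodal=is_multimodal,
        subclonal_fraction=subclonal_fraction,
        mixture=mixture,
        wgd=wgd,
        flags=flags,
    )
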