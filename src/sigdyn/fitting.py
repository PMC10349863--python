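"""Signature refitting: estimate per-sample exposures of known signatures.

The refit is a constrained regression of each sample's normalized channel
spectrum on the reference matrix: non-negative least squares, renormalize,
zero every contribution below the confidence threshold (default 5% — below
that, caller concordance makes contributions unreliable), then refit
restricted to the surviving signatures. Deficiency phenotypes (HR,
colibactin, MMR) are called from thresholded SBS and ID exposures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .io import SignatureReference, ValidationError


@dataclass
class ExposureTable:
    """Per-sample relative and absolute signature exposures.

    ``fractions`` rows sum to 1 over the retained signatures (all-zero for
    empty samples); ``absolute`` = fractions x per-sample mutation count;
    ``residual`` is the Euclidean distance between the observed and
    reconstructed normalized spectra (NaN for empty samples).
    """

    fractions: pd.DataFrame
    absolute: pd.DataFrame
    residual: pd.Series
    compartment: str = "all"

    @property
    def samples(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def signatures(self) -> list[str]:
        return list(self.fractions.columns)


class SignatureRefitter(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer mapping catalogues to signature exposures.

    Parameters
    ----------
    reference : SignatureReference
        Channel x signature probability matrix (COSMIC layout).
    threshold : float, default 0.05
        Relative contributions below this are set to exactly 0 and the
        remaining signatures refit.

    Attributes (after ``fit``)
    --------------------------
    exposures_ : ExposureTable for the training catalogue.
    """

    def __init__(self, reference: SignatureReference, threshold: float = 0.05):
        self.reference = reference
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None) -> "SignatureRefitter":
        self.exposures_ = fit_cohort(X, self.reference, self.threshold)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Exposure fractions (samples x signatures) for catalogue ``X``."""
        return fit_cohort(X, self.reference, self.threshold).fractions

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).exposures_.fractions


def fit_exposures(
    counts: np.ndarray | pd.Series,
    reference: SignatureReference,
    threshold: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Exposure fractions of one catalogue row, plus reconstruction residual.

    Stages: NNLS on the normalized spectrum; renormalize weights; zero
    weights < threshold; NNLS refit restricted to survivors; renormalize.
    A zero-count row yields all-zero exposures and NaN residual.
    """
    if isinstance(counts, pd.Series):
        if list(counts.index) != reference.channels:
            raise ValidationError("catalogue channels do not match reference channels")
        counts = counts.to_numpy()
    counts = np.asarray(counts, dtype=float)
    M = reference.values()
    if counts.shape != (M.shape[0],):
        raise ValidationError(
            f"catalogue row has {counts.shape[0]} channels, reference {M.shape[0]}"
        )
    total = counts.sum()
    k = M.shape[1]
    if total <= 0:
        return np.zeros(k), float("nan")
    v = counts / total

    w, _ = nnls(M, v)
    if w.sum() <= 0:
        return np.zeros(k), float(np.linalg.norm(v))
    frac = w / w.sum()
    keep = frac >= threshold
    if not keep.any():
        keep[np.argmax(frac)] = True
    w2, _ = nnls(M[:, keep], v)
    out = np.zeros(k)
    if w2.sum() > 0:
        out[keep] = w2 / w2.sum()
        recon_w = np.zeros(k)
        recon_w[keep] = w2
    else:  # pathological: fall back to the unthresholded fit
        out = frac
        recon_w = w
    residual = float(np.linalg.norm(v - M @ recon_w))
    return out, residual


def fit_cohort(
    catalogue: pd.DataFrame,
    reference: SignatureReference,
    threshold: float = 0.05,
    compartment: str = "all",
) -> ExposureTable:
    """Row-wise refit of a samples x channels catalogue."""
    if list(catalogue.columns) != reference.channels:
        raise ValidationError("catalogue channels do not match reference channels")
    fracs, resids = [], []
    for _, row in catalogue.iterrows():
        f, r = fit_exposures(row.to_numpy(), reference, threshold)
        fracs.append(f)
        resids.append(r)
    fractions = pd.DataFrame(fracs, index=catalogue.index, columns=reference.signatures)
    absolute = fractions.mul(catalogue.sum(axis=1), axis=0)
    residual = pd.Series(resids, index=catalogue.index, name="residual")
    return ExposureTable(fractions, absolute, residual, compartment)


# ---------------------------------------------------------------------------
# deficiency calls
# ---------------------------------------------------------------------------

@dataclass
class DeficiencyRules:
    """Thresholded-exposure rules for repair-deficiency phenotypes.

    Defaults follow the conservative >5% convention: HR deficiency requires
    SBS3, SBS8, ID6 and ID8 all above 5%; colibactin exposure requires both
    SBS41 and ID18 above 5%; MMR deficiency requires SBS44 above 5%.
    """

    threshold: float = 0.05
    hrd_sbs: tuple[str, ...] = ("SBS3", "SBS8")
    hrd_id: tuple[str, ...] = ("ID6", "ID8")
    colibactin_sbs: tuple[str, ...] = ("SBS41",)
    colibactin_id: tuple[str, ...] = ("ID18",)
    mmrd_sbs: tuple[str, ...] = ("SBS44",)
    mmrd_id: tuple[str, ...] = ()


class ConfigurationError(ValueError):
    pass


def call_deficiencies(
    sbs_exposures: pd.DataFrame,
    id_exposures: pd.DataFrame,
    rules: DeficiencyRules | None = None,
) -> pd.DataFrame:
    """Per-sample boolean flags {HRD, colibactin, MMRd} from exposure tables."""
    rules = rules or DeficiencyRules()
    samples = sbs_exposures.index
    if not samples.equals(id_exposures.index):
        common = samples.intersection(id_exposures.index)
        if len(common) == 0:
            raise ValidationError("SBS and ID exposure tables share no samples")
        samples = common

    def above(table: pd.DataFrame, sigs: tuple[str, ...]) -> pd.Series:
        missing = [s for s in sigs if s not in table.columns]
        if missing:
            raise ConfigurationError(f"rule references absent signatures: {missing}")
        if not sigs:
            return pd.Series(True, index=samples)
        return (table.loc[samples, list(sigs)] > rules.threshold).all(axis=1)

    return pd.DataFrame(
        {
            "HRD": above(sbs_exposures, rules.hrd_sbs) & above(id_exposures, rules.hrd_id),
            "colibactin": above(sbs_exposures, rules.colibactin_sbs)
            & above(id_exposures, rules.colibactin_id),
            "MMRd": above(sbs_exposures, rules.mmrd_sbs) & above(id_exposures, rules.mmrd_id),
        },
        index=samples,
    )
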