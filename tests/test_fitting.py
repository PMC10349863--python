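import numpy as np
import pandas as pd
import pytest

from sigdyn._channels import SBS96_CHANNELS
from sigdyn.fitting import (
    ConfigurationError,
    DeficiencyRules,
    SignatureRefitter,
    call_deficiencies,
    fit_cohort,
    fit_exposures,
)
from sigdyn.io import SignatureReference, ValidationError, make_signature_reference

from _oracles import simplex_grid_oracle


def _two_sig_ref(sbs_ref, a="SBS2", b="SBS17b"):
    return make_signature_reference(sbs_ref.matrix[[a, b]], "sbs96")


class TestFitExposures:
    def test_exactly_representable_row(self, sbs_ref):
        ref = _two_sig_ref(sbs_ref)
        row = 1000 * ref.matrix["SBS2"].to_numpy()
        f, resid = fit_exposures(row, ref)
        assert f[0] == pytest.approx(1.0, abs=1e-9)
        assert f[1] == 0.0
        assert resid < 1e-6

    def test_mixture_recovery_matches_grid_oracle(self, sbs_ref):
        """Planted 0.70/0.30 mixture at n = 10,000: within 0.03 of truth and
        0.01 of the simplex grid-search oracle."""
        ref = _two_sig_ref(sbs_ref)
        pa = ref.matrix["SBS2"].to_numpy()
        pb = ref.matrix["SBS17b"].to_numpy()
        rng = np.random.default_rng(1)
        counts = rng.multinomial(10_000, 0.7 * pa + 0.3 * pb)
        f, _ = fit_exposures(counts, ref)
        assert abs(f[0] - 0.7) < 0.03
        w_oracle = simplex_grid_oracle(counts, pa, pb, resolution=0.01)
        assert abs(f[0] - w_oracle) <= 0.011

    def test_small_contributions_zeroed_and_refit(self, sbs_ref):
        """A raw fit of roughly {0.93, 0.04, 0.03} collapses to the dominant
        signature after 5% thresholding."""
        ref = make_signature_reference(sbs_ref.matrix[["SBS1", "SBS2", "SBS18"]], "sbs96")
        m = ref.values()
        v = 0.93 * m[:, 0] + 0.04 * m[:, 1] + 0.03 * m[:, 2]
        f, _ = fit_exposures(10_000 * v, ref, threshold=0.05)
        assert f[1] == 0.0 and f[2] == 0.0
        assert f[0] == pytest.approx(1.0)

    def test_zero_count_row(self, sbs_ref):
        f, resid = fit_exposures(np.zeros(96), sbs_ref)
        assert np.all(f == 0.0)
        assert np.isnan(resid)

    def test_channel_mismatch_rejected(self, sbs_ref):
        row = pd.Series(np.ones(96), index=list(SBS96_CHANNELS)[::-1])
        with pytest.raises(ValidationError):
            fit_exposures(row, sbs_ref)

    def test_thresholding_is_idempotent(self, sbs_ref):
        """Refitting the reconstruction re-yields the surviving set."""
        rng = np.random.default_rng(7)
        m = sbs_ref.values()
        mix = 0.55 * m[:, 6] + 0.35 * m[:, 0] + 0.10 * m[:, 1]
        counts = rng.multinomial(8000, mix)
        f1, _ = fit_exposures(counts, sbs_ref)
        recon = m @ f1
        f2, _ = fit_exposures(10_000 * recon, sbs_ref)
        assert set(np.nonzero(f1)[0]) == set(np.nonzero(f2)[0])
        assert np.allclose(f1, f2, atol=0.02)

    def test_residual_not_worse_with_superset_reference(self, sbs_ref):
        """Adding unused signatures to the reference cannot increase the
        reconstruction residual of the unthresholded fit."""
        rng = np.random.default_rng(9)
        small = make_signature_reference(sbs_ref.matrix[["SBS17b", "SBS1"]], "sbs96")
        counts = rng.multinomial(
            5000, 0.6 * small.values()[:, 0] + 0.4 * small.values()[:, 1]
        )
        _, r_small = fit_exposures(counts, small, threshold=0.0)
        _, r_full = fit_exposures(counts, sbs_ref, threshold=0.0)
        assert r_full <= r_small + 1e-12


class TestRefitterEstimator:
    def test_transform_returns_fractions(self, sbs_ref):
        rng = np.random.default_rng(2)
        m = sbs_ref.values()
        rows = [rng.multinomial(3000, m[:, i]) for i in (0, 6)]
        X = pd.DataFrame(rows, index=["a", "b"], columns=sbs_ref.channels)
        est = SignatureRefitter(sbs_ref).fit(X)
        fr = est.transform(X)
        assert fr.shape == (2, len(sbs_ref.signatures))
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-6)
        assert est.exposures_.fractions.equals(fr)
        assert est.get_params()["threshold"] == 0.05

    def test_identical_rows_identical_exposures(self, sbs_ref):
        m = sbs_ref.values()
        row = np.round(2000 * (0.5 * m[:, 0] + 0.5 * m[:, 5]))
        X = pd.DataFrame([row, row], index=["a", "b"], columns=sbs_ref.channels)
        table = fit_cohort(X, sbs_ref)
        assert table.fractions.loc["a"].equals(table.fractions.loc["b"])
        assert np.allclose(
            table.absolute.loc["a"].sum(), X.loc["a"].sum(), atol=1e-6
        )


class TestDeficiencyCalls:
    def _tables(self, sbs_vals, id_vals):
        sbs = pd.DataFrame(sbs_vals, index=["s"])
        idt = pd.DataFrame(id_vals, index=["s"])
        return sbs, idt

    def test_hrd_requires_all_four_signatures(self):
        sbs, idt = self._tables(
            {"SBS3": [0.06], "SBS8": [0.06], "SBS41": [0.0], "SBS44": [0.0]},
            {"ID6": [0.07], "ID8": [0.06], "ID18": [0.0]},
        )
        flags = call_deficiencies(sbs, idt)
        assert bool(flags.loc["s", "HRD"]) is True
        # dropping one component below threshold switches the call off
        sbs.loc["s", "SBS8"] = 0.04
        assert not call_deficiencies(sbs, idt).loc["s", "HRD"]

    def test_colibactin_needs_both_snv_and_indel_evidence(self):
        sbs, idt = self._tables(
            {"SBS3": [0.0], "SBS8": [0.0], "SBS41": [0.06], "SBS44": [0.0]},
            {"ID6": [0.0], "ID8": [0.0], "ID18": [0.08]},
        )
        assert bool(call_deficiencies(sbs, idt).loc["s", "colibactin"]) is True
        idt.loc["s", "ID18"] = 0.05  # strict inequality: 5% exactly fails
        assert not call_deficiencies(sbs, idt).loc["s", "colibactin"]

    def test_mmrd_threshold_semantics(self):
        sbs, idt = self._tables(
            {"SBS3": [0.0], "SBS8": [0.0], "SBS41": [0.0], "SBS44": [0.04]},
            {"ID6": [0.0], "ID8": [0.0], "ID18": [0.0]},
        )
        assert not call_deficiencies(sbs, idt).loc["s", "MMRd"]
        sbs.loc["s", "SBS44"] = 0.051
        assert bool(call_deficiencies(sbs, idt).loc["s", "MMRd"]) is True

    def test_missing_rule_signature_is_configuration_error(self):
        sbs = pd.DataFrame({"SBS3": [0.9]}, index=["s"])
        idt = pd.DataFrame({"ID6": [0.9]}, index=["s"])
        with pytest.raises(ConfigurationError):
            call_deficiencies(sbs, idt)

    def test_rules_are_overridable(self):
        sbs = pd.DataFrame({"SBS3": [0.06]}, index=["s"])
        idt = pd.DataFrame({"ID6": [0.06]}, index=["s"])
        rules = DeficiencyRules(hrd_sbs=("SBS3",), hrd_id=("ID6",),
                                colibactin_sbs=(), colibactin_id=(),
                                mmrd_sbs=(), mmrd_id=())
        flags = call_deficiencies(sbs, idt, rules)
        assert bool(flags.loc["s", "HRD"]) is True
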