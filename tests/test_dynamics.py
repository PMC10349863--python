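from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sigdyn.dynamics import (
    bh_adjust,
    build_stage_features,
    compare_groups,
    dominance_groups,
    subclonal_shifts,
)


class TestSubclonalShifts:
    def _tables(self):
        clonal = pd.DataFrame({"SBS17b": [0.40, 0.30], "SBS1": [0.60, 0.70]},
                              index=["s1", "s2"])
        subclonal = pd.DataFrame({"SBS17b": [0.25, 0.30], "SBS1": [0.75, 0.70]},
                                 index=["s1", "s2"])
        return clonal, subclonal

    def test_delta_arithmetic(self):
        clonal, subclonal = self._tables()
        table = subclonal_shifts(clonal, subclonal)
        assert table.deltas.loc["s1", "SBS17b"] == pytest.approx(-0.15)
        assert table.deltas.loc["s1", "SBS1"] == pytest.approx(0.15)

    def test_identical_compartments_give_zero(self):
        clonal, _ = self._tables()
        table = subclonal_shifts(clonal, clonal.copy())
        assert (table.deltas == 0).all().all()

    def test_small_compartment_masked(self):
        clonal, subclonal = self._tables()
        counts = pd.Series({"s1": 200, "s2": 10})
        table = subclonal_shifts(clonal, subclonal, subclonal_counts=counts)
        assert table.deltas.loc["s2"].isna().all()
        assert table.deltas.loc["s1"].notna().all()

    def test_stage_summary_medians(self):
        clonal, subclonal = self._tables()
        stage = pd.Series({"s1": "primary", "s2": "primary"})
        table = subclonal_shifts(clonal, subclonal, stage=stage)
        summary = table.stage_summary().set_index(["stage", "signature"])
        assert summary.loc[("primary", "SBS17b"), "median"] == pytest.approx(-0.075)

    def test_null_shift_is_unbiased(self, genome, sbs_ref):
        """Equal compartments drawn independently: mean shift within 0.02."""
        rng = np.random.default_rng(7)
        m = sbs_ref.values()
        mix = 0.5 * m[:, sbs_ref.signatures.index("SBS17b")] + \
            0.5 * m[:, sbs_ref.signatures.index("SBS1")]
        from sigdyn.fitting import fit_cohort
        rows_a = [rng.multinomial(2000, mix) for _ in range(50)]
        rows_b = [rng.multinomial(2000, mix) for _ in range(50)]
        idx = [f"s{i}" for i in range(50)]
        fa = fit_cohort(pd.DataFrame(rows_a, index=idx, columns=sbs_ref.channels), sbs_ref)
        fb = fit_cohort(pd.DataFrame(rows_b, index=idx, columns=sbs_ref.channels), sbs_ref)
        table = subclonal_shifts(fa.fractions, fb.fractions)
        for sig in ("SBS17b", "SBS1"):
            assert abs(table.deltas[sig].mean()) < 0.02


def _exact_ranksum_p(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n, k = len(pooled), len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:k].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(n), k)]
    mu = np.mean(sums)
    count = sum(1 for s in sums if abs(s - mu) >= abs(obs - mu) - 1e-9)
    return count / len(sums)


class TestCompareGroups:
    def test_exact_ranksum_example(self):
        out = compare_groups({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert out.loc[0, "p"] == pytest.approx(0.1)

    def test_matches_enumeration_for_small_groups(self):
        rng = np.random.default_rng(2)
        for _ in range(6):
            x = rng.normal(0, 1, int(rng.integers(3, 7)))
            y = rng.normal(0.5, 1, int(rng.integers(3, 7)))
            out = compare_groups({"a": x, "b": y})
            assert out.loc[0, "p"] == pytest.approx(_exact_ranksum_p(x, y), abs=1e-9)

    def test_identical_groups_give_p_one(self):
        out = compare_groups({"a": [1.0, 1, 1], "b": [1.0, 1, 1]})
        assert out.loc[0, "p"] == 1.0 and out.loc[0, "flag"] == "all-tied"

    def test_paired_signed_rank(self):
        out = compare_groups({"pre": [1.0, 2, 3, 4], "post": [2.0, 3, 4, 5]}, paired=True)
        assert out.loc[0, "p"] < 0.2  # consistent one-directional change
        tied = compare_groups({"pre": [1.0, 2, 3], "post": [1.0, 2, 3]}, paired=True)
        assert tied.loc[0, "p"] == 1.0

    def test_bh_adjustment_hand_computation(self):
        q = bh_adjust([0.01, 0.02, 0.04])
        assert np.allclose(q, [0.03, 0.03, 0.04])

    def test_bh_column_added_across_family(self):
        out = compare_groups(
            {"a": [1.0, 2, 3], "b": [4.0, 5, 6], "c": [7.0, 8, 9]}, adjust="BH"
        )
        assert "q" in out.columns and len(out) == 3
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_too_small_groups_raise(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1, 2], "b": [3, 4, 5]})


class TestDominance:
    def test_majority_is_dominant(self):
        exp = pd.DataFrame({"SBS17a": [0.30], "SBS17b": [0.25], "SBS1": [0.45]},
                           index=["s"])
        assert dominance_groups(exp, {"SBS17a", "SBS17b"})["s"] == "dominant"

    def test_exact_half_is_not_dominant(self):
        exp = pd.DataFrame({"SBS17a": [0.25], "SBS17b": [0.25], "SBS1": [0.5]},
                           index=["s"])
        assert dominance_groups(exp, {"SBS17a", "SBS17b"})["s"] == "other"

    def test_empty_set_never_dominant(self):
        exp = pd.DataFrame({"SBS17a": [0.9]}, index=["s"])
        assert (dominance_groups(exp, set()) == "other").all()


class TestStageFeatures:
    def _exposures(self, n_sigs=12, n=5):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(n_sigs), size=n)
        return pd.DataFrame(raw, index=[f"s{i}" for i in range(n)],
                            columns=[f"SBS{i}" for i in range(n_sigs)])

    def test_overall_mode_column_count(self):
        exp = self._exposures()
        summary = pd.DataFrame(
            {"subclonal_fraction": 0.2, "early_fraction": 0.5}, index=exp.index
        )
        feats = build_stage_features(exp, clonality_summary=summary, mode="overall")
        assert feats.shape[1] == 14  # 12 signatures + 2 clonality covariates

    def test_split_mode_column_count(self):
        exp = self._exposures()
        comp = {c: exp.copy() for c in ("clonal_early", "clonal_late", "subclonal")}
        feats = build_stage_features(exp, compartment_exposures=comp,
                                     mode="compartment_split")
        assert feats.shape[1] == 36  # 12 signatures x 3 compartments

    def test_missing_compartment_gets_indicator(self):
        exp = self._exposures()
        comp = {
            "clonal_early": exp.copy(),
            "clonal_late": exp.copy(),
            "subclonal": exp.iloc[:2].copy(),  # missing for 3 samples
        }
        feats = build_stage_features(exp, compartment_exposures=comp,
                                     mode="compartment_split")
        assert "subclonal:missing" in feats.columns
        assert feats["subclonal:missing"].sum() == 3
        assert feats.loc["s4", [c for c in feats.columns
                               if c.startswith("subclonal:SBS")]].sum() == 0

    def test_rows_align_with_input_order(self):
        exp = self._exposures()
        feats = build_stage_features(exp, mode="overall")
        assert list(feats.index) == list(exp.index)
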