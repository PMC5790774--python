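import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

import thprof as tp
from thprof.diffreg import (
    DOWN,
    UNCHANGED,
    UP,
    DifferentialExpressionClassifier,
    classify_regulation,
    signed_fold_change,
)
from thprof.diffreg import test_two_groups as welch_p  # alias: avoid pytest collection

positive = st.floats(min_value=0.01, max_value=1e6, allow_nan=False)


class TestSignedFoldChange:
    def test_doubling(self):
        assert signed_fold_change(20, 10) == pytest.approx(2.0)

    def test_down_regulation_sign_convention(self):
        assert signed_fold_change(10, 12.8) == pytest.approx(-1.28)

    def test_identity_is_plus_one(self):
        assert signed_fold_change(7.3, 7.3) == pytest.approx(1.0)

    def test_negative_means_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            signed_fold_change(-1, 5)

    def test_zero_zero_is_error_not_silent_one(self):
        with pytest.raises(ValueError, match="zero"):
            signed_fold_change(0, 0)

    def test_single_zero_mean_requires_pseudocount(self):
        with pytest.raises(ValueError, match="pseudo-count"):
            signed_fold_change(5, 0)
        assert signed_fold_change(5, 0, epsilon=0.5) == pytest.approx(5.5 / 0.5)

    @given(positive, positive)
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, a, b):
        fwd = signed_fold_change(a, b)
        rev = signed_fold_change(b, a)
        assert abs(fwd) >= 1 and abs(rev) >= 1
        if a != b:
            assert fwd == pytest.approx(-rev, rel=1e-9)


class TestTwoGroupTest:
    def test_identical_groups_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert welch_p(x, x) > 0.99

    def test_flat_equal_groups_p_one(self):
        assert welch_p([3, 3, 3], [3, 3, 3]) == 1.0

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        assert welch_p(a, b) == pytest.approx(welch_p(b, a))

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            welch_p([1.0], [1.0, 2.0])

    def test_planted_fourfold_shift_is_almost_always_significant(self):
        """A 4-fold shift at n=5 and low noise clears alpha in >=95% of draws."""
        rng = np.random.default_rng(42)
        hits = 0
        n_draws = 1000
        for _ in range(n_draws):
            control = rng.lognormal(np.log(100), 0.1, 5)
            case = rng.lognormal(np.log(400), 0.1, 5)
            hits += welch_p(case, control) < 0.05
        assert hits / n_draws >= 0.95


class TestClassifyRegulation:
    @pytest.mark.parametrize(
        "sfc, p, fc_min, alpha, expected",
        [
            (1.33, 0.01, 1.2, 0.05, UP),      # sub-2-fold but significant
            (3.0, 0.20, 1.2, 0.05, UNCHANGED),  # significance gate
            (1.0, 0.001, 1.0, 0.05, UNCHANGED),  # exact no-change boundary
            (-1.24, 0.01, 1.2, 0.05, DOWN),
            (-1.1, 0.01, 1.2, 0.05, UNCHANGED),  # below fold gate
            (2.0, None, 1.2, 0.05, UP),       # pre-gated table: no p needed
        ],
    )
    def test_rule_table(self, sfc, p, fc_min, alpha, expected):
        assert classify_regulation(sfc, p, fc_min, alpha) == expected

    def test_fc_min_below_one_rejected(self):
        with pytest.raises(ValueError, match="fc_min"):
            classify_regulation(2.0, 0.01, fc_min=0.5)

    @given(st.floats(1.0, 50.0), st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_sfc(self, magnitude, p):
        """Raising sfc (p fixed) never moves the call from UP toward DOWN."""
        order = {DOWN: -1, UNCHANGED: 0, UP: 1}
        lo = classify_regulation(-magnitude, p)
        hi = classify_regulation(magnitude, p)
        assert order[hi] >= order[lo]


class TestDiffTable:
    def test_identical_matrices_all_unchanged(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.lognormal(4, 1, (30, 5)),
                         index=[f"g{i}" for i in range(30)])
        table = tp.diff_table(m, m.copy())
        assert (table.records.call == UNCHANGED).all()

    def test_row_permutation_permutes_records(self):
        case, control, _ = tp.simulate_case_control(
            tp.CaseControlSimConfig(n_genes=50), seed=3)
        base = tp.diff_table(case, control)
        perm = case.index[::-1]
        permuted = tp.diff_table(case.loc[perm], control.loc[perm])
        assert permuted.records.loc[base.genes].call.equals(base.records.call)

    def test_gene_axis_mismatch_rejected(self):
        a = pd.DataFrame(np.ones((2, 3)), index=["x", "y"])
        b = pd.DataFrame(np.ones((2, 3)), index=["x", "z"])
        with pytest.raises(ValueError, match="gene axis"):
            tp.diff_table(a, b)

    def test_log2_scale_matches_linear(self):
        case, control, _ = tp.simulate_case_control(
            tp.CaseControlSimConfig(n_genes=40), seed=4)
        linear = tp.diff_table(case, control, fc_min=1.5)
        logged = tp.diff_table(np.log2(case), np.log2(control), fc_min=1.5, scale="log2")
        # fold changes agree; p-values differ (test runs on the stated scale)
        assert np.allclose(linear.records.sfc, logged.records.sfc)

    def test_scale_flag_is_mandatoryish(self):
        a = pd.DataFrame(np.ones((2, 3)), index=["x", "y"])
        with pytest.raises(ValueError, match="scale"):
            tp.diff_table(a, a, scale="auto")

    def test_simulator_truth_recovered(self):
        case, control, truth = tp.simulate_case_control(seed=5)
        table = tp.diff_table(case, control, fc_min=1.5)
        merged = table.records.join(truth)
        planted = merged[merged.planted_call != UNCHANGED]
        assert (planted.call == planted.planted_call).mean() >= 0.9


class TestEstimator:
    def test_vectorised_fit_agrees_with_scalar_functions(self):
        rng = np.random.default_rng(11)
        case = pd.DataFrame(rng.lognormal(3, 1, (25, 4)).T,
                            columns=[f"g{i}" for i in range(25)])
        control = pd.DataFrame(rng.lognormal(3, 1, (25, 4)).T,
                               columns=case.columns)
        X = pd.concat([case, control])
        y = ["case"] * 4 + ["control"] * 4
        clf = DifferentialExpressionClassifier().fit(X, y)
        for j, g in enumerate(case.columns):
            sfc = signed_fold_change(case[g].mean(), control[g].mean())
            p = welch_p(case[g], control[g])
            assert clf.fold_change_[j] == pytest.approx(sfc)
            assert clf.p_value_[j] == pytest.approx(p)
            assert clf.call_[j] == classify_regulation(sfc, p)

    def test_sklearn_clone_and_params(self):
        clf = DifferentialExpressionClassifier(fc_min=1.5, alpha=0.01, correction="bh")
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()

    def test_bh_correction_is_more_conservative(self):
        case, control, _ = tp.simulate_case_control(
            tp.CaseControlSimConfig(n_genes=300, frac_up=0.05, frac_down=0.05,
                                    effect_fold=1.6, cv=0.3), seed=6)
        raw = tp.diff_table(case, control)
        bh = tp.diff_table(case, control, correction="bh")
        n_calls = lambda t: (t.records.call != UNCHANGED).sum()
        assert n_calls(bh) <= n_calls(raw)

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            DifferentialExpressionClassifier().predict()


class TestSignedTables:
    def test_packaged_contrasts(self):
        tables = tp.load_mhc2_diff_tables()
        gata3 = tables["gata3_ko"]
        assert gata3.call("Cd74") == UP
        assert gata3.records.at["Cd74", "sfc"] == pytest.approx(1.33)
        hdac6 = tables["hdac6_ko"]
        assert hdac6.call("Ciita") == DOWN
        assert hdac6.records.at["Ciita", "sfc"] == pytest.approx(-1.24)
        for t in tables.values():
            assert t.call("H2-DMb1") == UNCHANGED

    def test_sub_unit_magnitude_rejected(self):
        with pytest.raises(ValueError, match="signed-convention"):
            tp.load_signed_table({"g1": 0.8})

    def test_blank_means_unchanged(self):
        table = tp.load_signed_table({"g1": None, "g2": "", "g3": np.nan, "g4": -2.0})
        assert list(table.records.call) == [UNCHANGED, UNCHANGED, UNCHANGED, DOWN]


class TestGeneSetCounts:
    def test_mhc2_tallies(self):
        tables = tp.load_mhc2_diff_tables()
        mhc2 = tp.load_gene_set("mhc2_mouse")
        counts = {k: tp.geneset_regulation_counts(t, mhc2) for k, t in tables.items()}
        assert counts["gata3_ko"].n_up == 7
        assert counts["bcl6_ko"].n_up == 5
        assert counts["hdac6_ko"].n_down == 5

    def test_count_conservation(self):
        tables = tp.load_mhc2_diff_tables()
        mhc2 = tp.load_gene_set("mhc2_mouse")
        for t in tables.values():
            c = tp.geneset_regulation_counts(t, mhc2)
            assert c.total == len(mhc2) == 14

    def test_unmeasured_members_counted(self):
        table = tp.load_signed_table({"Cd74": 2.0})
        gs = tp.load_gene_set("mhc2_mouse")
        c = tp.geneset_regulation_counts(table, gs)
        assert c.n_unmeasured == 13 and c.n_up == 1

    def test_all_unchanged_gives_zero_counts(self):
        table = tp.load_signed_table({g: None for g in tp.load_gene_set("mhc2_mouse").genes})
        c = tp.geneset_regulation_counts(table, tp.load_gene_set("mhc2_mouse"))
        assert c.n_up == 0 and c.n_down == 0 and c.n_unchanged == 14
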