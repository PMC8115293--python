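"""qPCR relative expression, signature scoring, splits, survival plumbing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecmquant import synthgen
from ecmquant.scores import (
    CtRecord,
    binarize_histology,
    fold_change,
    km_logrank,
    maf_score,
    median_split,
    relative_expression,
    strip_collagen_genes,
)


class TestRelativeExpression:
    def test_delta_ct_zero_gives_unity(self):
        assert relative_expression(CtRecord(23.0, (22.0, 24.0))) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # ct 20 against housekeepers (22, 24): delta = -3, RE = 2^3
        assert relative_expression(CtRecord(20.0, (22.0, 24.0))) == pytest.approx(8.0)

    def test_one_cycle_halves_expression(self):
        r1 = relative_expression(CtRecord(20.0, (21.0,)))
        r2 = relative_expression(CtRecord(21.0, (21.0,)))
        assert r2 == pytest.approx(r1 / 2)

    def test_empty_housekeepers_rejected(self):
        with pytest.raises(ValueError):
            CtRecord(20.0, ())

    def test_fold_change_identities(self):
        assert fold_change(2.0, 2.0) == 1.0
        assert fold_change(4.0, 2.0) == 2.0
        assert fold_change(2.0, 4.0) == pytest.approx(1 / fold_change(4.0, 2.0))


class TestMafScore:
    def test_equal_values_give_that_value(self):
        df = pd.DataFrame({"s1": [3.0, 3.0, 3.0]}, index=["A", "B", "C"])
        assert maf_score(df, ["A", "B", "C"])["s1"] == pytest.approx(3.0)

    def test_hand_geometric_mean(self):
        df = pd.DataFrame({"s1": [1.0, 2.0, 4.0]}, index=["A", "B", "C"])
        assert maf_score(df, ["A", "B", "C"])["s1"] == pytest.approx(2.0)

    def test_matches_exp_mean_log_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mat = rng.uniform(0.1, 12.0, size=(8, 5))
            df = pd.DataFrame(mat, index=[f"g{i}" for i in range(8)],
                              columns=[f"s{j}" for j in range(5)])
            oracle = np.exp(np.mean(np.log(mat), axis=0))
            assert np.allclose(maf_score(df, df.index).to_numpy(), oracle, atol=1e-9)

    def test_missing_genes_dropped_with_warning(self, caplog):
        df = pd.DataFrame({"s1": [2.0, 8.0]}, index=["A", "B"])
        with caplog.at_level("WARNING"):
            s = maf_score(df, ["A", "B", "NOT_THERE"])
        assert "NOT_THERE" in caplog.text
        assert s["s1"] == pytest.approx(4.0)

    def test_all_genes_missing_rejected(self):
        df = pd.DataFrame({"s1": [2.0]}, index=["A"])
        with pytest.raises(ValueError):
            maf_score(df, ["X", "Y"])

    def test_scale_consistency(self):
        rng = np.random.default_rng(1)
        mat = rng.uniform(0.5, 5.0, size=(6, 4))
        df = pd.DataFrame(mat, index=list("ABCDEF"))
        s1 = maf_score(df, list("ABCDEF"))
        s2 = maf_score(df * 2.5, list("ABCDEF"))
        assert np.allclose(s2.to_numpy(), 2.5 * s1.to_numpy())


class TestMedianSplit:
    def test_four_scores(self):
        g = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert list(g) == ["low", "low", "high", "high"]

    def test_all_equal_all_low(self):
        g = median_split(pd.Series([2.0, 2.0, 2.0]))
        assert set(g) == {"low"}

    def test_single_sample_low(self):
        assert median_split(pd.Series([5.0]))[0] == "low"

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=40, unique=True))
    @settings(max_examples=100, derandomize=True)
    def test_invariant_under_monotone_transform(self, vals):
        s = pd.Series(vals)
        assert list(median_split(s)) == list(median_split(np.log(s)))

    @given(st.lists(st.floats(0.1, 100.0), min_size=2, max_size=41, unique=True))
    @settings(max_examples=100, derandomize=True)
    def test_group_sizes_differ_by_at_most_one(self, vals):
        counts = median_split(pd.Series(vals)).value_counts()
        assert abs(counts.get("high", 0) - counts.get("low", 0)) <= 1


class TestStripCollagen:
    def test_removes_collagen_symbols(self):
        kept, removed = strip_collagen_genes(["COL1A1", "ACTA2"])
        assert kept == ["ACTA2"] and removed == ["COL1A1"]

    def test_identity_without_collagen(self):
        kept, removed = strip_collagen_genes(["ACTA2", "FAP", "COLLAGEN_LIKE"])
        assert kept == ["ACTA2", "FAP", "COLLAGEN_LIKE"] and removed == []

    def test_all_collagen_empties_signature(self):
        kept, removed = strip_collagen_genes(["COL1A1", "COL1A2", "COL6A3"])
        assert kept == [] and len(removed) == 3


class TestBinarizeHistology:
    @pytest.mark.parametrize("score,expected", [(2, "low"), (3, "high"), (0, "low"), (4, "high")])
    def test_invasion_cut(self, score, expected):
        assert binarize_histology("invasion", score) == expected

    @pytest.mark.parametrize("grade,expected", [("3+", "CSD"), ("2", "CSD"), ("2-", "noCSD"), ("0", "noCSD")])
    def test_elastosis_cut(self, grade, expected):
        assert binarize_histology("elastosis", grade) == expected

    def test_elastosis_integer_index(self):
        assert binarize_histology("elastosis", 5) == "noCSD"
        assert binarize_histology("elastosis", 6) == "CSD"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_histology("invasion", 5)


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        surv = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0], "event": [1, 1, 1, 1, 1, 1]},
            index=list("abcdef"),
        )
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
        res = km_logrank(groups, surv)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_matches_hand_risk_table(self):
        """Two groups with fully separated event times against a hand-built
        log-rank computation from the risk tables."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        grp = ["A", "A", "A", "B", "B", "B"]
        surv = pd.DataFrame({"time": times, "event": [1] * 6},
                            index=[f"s{i}" for i in range(6)])
        groups = pd.Series(grp, index=surv.index)

        # brute-force risk tables (all events distinct, one event per time)
        o_minus_e = 0.0
        var = 0.0
        for t in times:
            at_risk = [(ti, g) for ti, g in zip(times, grp) if ti >= t]
            n = len(at_risk)
            n_a = sum(1 for _, g in at_risk if g == "A")
            d = 1
            e_a = d * n_a / n
            o_a = 1.0 if grp[times.index(t)] == "A" else 0.0
            o_minus_e += o_a - e_a
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        expected_stat = o_minus_e**2 / var

        res = km_logrank(groups, surv)
        assert res.statistic == pytest.approx(expected_stat, rel=1e-6)

    def test_needs_two_groups_and_one_event(self):
        surv = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            km_logrank(pd.Series(["g", "g"], index=["a", "b"]), surv)
        surv0 = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            km_logrank(pd.Series(["g", "h"], index=["a", "b"]), surv0)


class TestParameterRecovery:
    def test_median_split_recovers_planted_groups(self):
        spec = synthgen.SurvivalSimSpec(seed=17)
        ds, truth = synthgen.make_expression_dataset(spec)
        score = maf_score(ds.values, spec.signature_genes)
        groups = median_split(score)
        agreement = float(np.mean(groups.values == truth.true_group.values))
        assert agreement >= 0.9

    def test_hazard_ratio_two_detected(self):
        """With a planted hazard ratio of 2 at n=200 the split is prognostic."""
        spec = synthgen.SurvivalSimSpec(seed=18)
        ds, _ = synthgen.make_expression_dataset(spec)
        groups = median_split(maf_score(ds.values, spec.signature_genes))
        res = km_logrank(groups, ds.survival)
        assert res.p_value < 0.05
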