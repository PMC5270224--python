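import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from hypervar import (
    ModerationParams,
    OmicsMatrix,
    Scale,
    bh_adjust,
    classify_features,
    combined_decision,
    estimate_moderation,
    paired_diffvar_test,
    rank_common,
    sex_diff_expression,
)
from hypervar.difftest import _trigamma_inverse, posterior_variance

CELLS = ("monocyte", "neutrophil", "naive_T")


def _absdev(arr, prefix="d"):
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
    )


class TestModeration:
    def test_trigamma_inverse_roundtrip(self):
        for x in (1e-4, 0.01, 0.5, 2.0, 50.0, 1e5):
            y = _trigamma_inverse(x)
            assert special.polygamma(1, y) == pytest.approx(x, rel=1e-8)

    def test_parameter_recovery(self, rng):
        d0, s0, df = 4.0, 1.0, 10
        sigma2 = d0 * s0 / rng.chisquare(d0, 10_000)
        s2 = sigma2 * rng.chisquare(df, 10_000) / df
        params = estimate_moderation(s2, df)
        assert 3.0 <= params.d0 <= 5.0
        assert 0.9 <= params.s0_sq <= 1.1

    def test_matches_limma_fixture(self):
        """Frozen oracle: Bioconductor limma fitFDist/squeezeVar on the
        identical variance vector gives d0=6.4062819902, s0^2=2.1204734168
        and first posterior variance 1.8208241845."""
        rng = np.random.default_rng(20240917)
        sigma2 = 6.0 * 2.0 / rng.chisquare(6.0, 300)
        s2 = sigma2 * rng.chisquare(12, 300) / 12
        params = estimate_moderation(s2, 12)
        assert params.d0 == pytest.approx(6.4062819902, abs=1e-8)
        assert params.s0_sq == pytest.approx(2.1204734168, abs=1e-8)
        assert posterior_variance(s2, params)[0] == pytest.approx(1.8208241845, abs=1e-8)

    def test_underdispersed_variances_shrink_completely(self):
        s2 = np.full(100, 2.5)
        params = estimate_moderation(s2, 10)
        assert math.isinf(params.d0)
        assert np.allclose(posterior_variance(s2, params), params.s0_sq)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_moderation(np.zeros(100), 10)
        with pytest.raises(ValueError, match="at least 50"):
            estimate_moderation(np.ones(10), 10)

    def test_posterior_variance_between_sample_and_prior(self, rng):
        s2 = rng.chisquare(5, 200) / 5
        params = estimate_moderation(s2, 5)
        post = posterior_variance(s2, params)
        lo = np.minimum(s2, params.s0_sq)
        hi = np.maximum(s2, params.s0_sq)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)


class TestPairedTest:
    def test_textbook_one_sample_t(self):
        a = _absdev([[1, 2, 3, 4]])
        b = _absdev([[0, 0, 0, 0]])
        res = paired_diffvar_test(a, b, moderation=ModerationParams.none(3))
        assert res["t"].iloc[0] == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2))
        assert res["t"].iloc[0] == pytest.approx(3.8730, abs=1e-4)
        assert res["df_total"].iloc[0] == 3

    def test_identical_deviations_give_null_result(self):
        a = _absdev([[1, 2, 3, 4, 5]])
        res = paired_diffvar_test(a, a.copy(), moderation=ModerationParams.none(4))
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_pairing_invariance_under_joint_permutation(self, rng):
        a = _absdev(rng.random((60, 12)))
        b = _absdev(rng.random((60, 12)))
        res1 = paired_diffvar_test(a, b)
        perm = rng.permutation(12)
        res2 = paired_diffvar_test(a.iloc[:, perm], b.iloc[:, perm])
        assert np.allclose(res1["t"], res2["t"])
        assert np.allclose(res1["p"], res2["p"])

    def test_unmoderated_equals_classical_paired_t(self, rng):
        a = _absdev(rng.random((1000, 20)))
        b = _absdev(rng.random((1000, 20)))
        res = paired_diffvar_test(a, b, moderation=ModerationParams.none(19))
        t_ref, p_ref = stats.ttest_rel(a.to_numpy(), b.to_numpy(), axis=1)
        assert np.max(np.abs(res["t"].to_numpy() - t_ref)) < 1e-10
        assert np.max(np.abs(res["p"].to_numpy() - p_ref)) < 1e-10

    def test_swapping_groups_negates_statistics(self, rng):
        a = _absdev(rng.random((100, 10)))
        b = _absdev(rng.random((100, 10)))
        ab = paired_diffvar_test(a, b)
        ba = paired_diffvar_test(b, a)
        assert np.allclose(ab["t"], -ba["t"])
        assert np.allclose(ab["mean_absdev_diff"], -ba["mean_absdev_diff"])
        assert np.allclose(ab["p"], ba["p"])

    def test_too_few_pairs_refused(self):
        a = _absdev([[1, 2, 3]])
        with pytest.raises(ValueError, match="pairs"):
            paired_diffvar_test(a, a.copy(), moderation=ModerationParams.none(2))


class TestBH:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    @staticmethod
    def brute_force(p):
        """min over tails of m * p_(j) / j, capped at 1."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        sorted_q = [min(1.0, min(m * p[order[j]] / (j + 1) for j in range(i, m))) for i in range(m)]
        q[order] = sorted_q
        return q

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 50))
            assert np.allclose(bh_adjust(p), self.brute_force(p), atol=1e-12)

    def test_nan_propagation(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        # NaN excluded from the family size m
        assert np.allclose(q[[0, 2]], self.brute_force([0.01, 0.02]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestCombinedDecision:
    def _call(self, q, ev_a, ev_b, mad_diff):
        # pooled EV range fixed to [0, 2] => delta = 0.2
        evs_a = np.array([ev_a, 0.0])
        evs_b = np.array([ev_b, 2.0])
        return combined_decision(
            np.array([q, 1.0]), evs_a, evs_b, np.array([mad_diff, 0.0]), "A", "B"
        ).iloc[0]

    def test_threshold_arithmetic(self):
        assert self._call(0.01, 0.45, 0.20, 1.0) == "A"  # ev_diff 0.25 >= 0.2
        assert self._call(0.01, 0.35, 0.20, 1.0) == "none"  # fails delta
        assert self._call(0.20, 0.70, 0.20, 1.0) == "none"  # fails alpha
        assert self._call(0.01, 0.20, 0.45, -1.0) == "B"

    def test_direction_agreement_required(self):
        assert self._call(0.01, 0.45, 0.20, -1.0) == "none"

    def test_degenerate_range_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            combined_decision([0.01], [1.0], [1.0], [0.5], "A", "B")


class TestClassification:
    @staticmethod
    def _truth_table_label(c_ab, c_ac, c_bc):
        """Independent hand enumeration of the classification rule."""
        a, b, c = CELLS

        def up(x, call_ab, call_ac, call_bc):
            if x == a:
                return (call_ab == a, call_ac == a)
            if x == b:
                return (call_ab == b, call_bc == b)
            return (call_ac == c, call_bc == c)

        for x in (a, b, c):
            u = up(x, c_ab, c_ac, c_bc)
            if u[0] and u[1]:
                return f"specific:{x}"
        if c_ac == a and c_bc == b:
            return f"shared:{a}+{b}"
        if c_ab == a and c_bc == c:
            return f"shared:{a}+{c}"
        if c_ab == b and c_ac == c:
            return f"shared:{b}+{c}"
        return "none"

    def test_exhaustive_enumeration_matches_truth_table(self):
        a, b, c = CELLS
        combos = list(itertools.product([a, b, "none"], [a, c, "none"], [b, c, "none"]))
        idx = pd.Index([f"g{i}" for i in range(len(combos))])
        calls = {
            (a, b): pd.Series([x[0] for x in combos], index=idx),
            (a, c): pd.Series([x[1] for x in combos], index=idx),
            (b, c): pd.Series([x[2] for x in combos], index=idx),
        }
        out = classify_features(calls, CELLS).set_index("feature_id")["label"]
        for i, combo in enumerate(combos):
            assert out.loc[f"g{i}"] == self._truth_table_label(*combo), combo

    def test_specific_requires_both_contrasts(self):
        a, b, c = CELLS
        idx = pd.Index(["g0"])
        calls = {
            (a, b): pd.Series([a], index=idx),
            (a, c): pd.Series([a], index=idx),
            (b, c): pd.Series(["none"], index=idx),
        }
        out = classify_features(calls, CELLS)
        assert out["label"].iloc[0] == f"specific:{a}"

    def test_labels_are_disjoint_on_random_calls(self, rng):
        a, b, c = CELLS
        n = 500
        idx = pd.Index([f"g{i}" for i in range(n)])
        for _ in range(20):
            calls = {
                (a, b): pd.Series(rng.choice([a, b, "none"], n), index=idx),
                (a, c): pd.Series(rng.choice([a, c, "none"], n), index=idx),
                (b, c): pd.Series(rng.choice([b, c, "none"], n), index=idx),
            }
            out = classify_features(calls, CELLS)
            assert len(out) == n  # one label per feature: disjoint by construction
            assert set(out["label"]) <= (
                {f"specific:{x}" for x in CELLS}
                | {f"shared:{x}+{y}" for x, y in itertools.combinations(CELLS, 2)}
                | {"none"}
            )

    def test_missing_contrast_is_an_error(self):
        a, b, c = CELLS
        calls = {(a, b): pd.Series(["none"], index=pd.Index(["g0"]))}
        with pytest.raises(ValueError, match="missing contrast"):
            classify_features(calls, CELLS)


class TestRankCommon:
    @staticmethod
    def _tables(mads, evs):
        idx = [f"g{i}" for i in range(len(next(iter(mads.values()))))]
        return {
            ct: pd.DataFrame({"feature_id": idx, "mad": mads[ct], "ev": evs[ct]})
            for ct in mads
        }

    def test_top_ranked_feature_always_selected(self, rng):
        mads = {ct: rng.random(20) for ct in CELLS}
        evs = {ct: rng.random(20) for ct in CELLS}
        for ct in CELLS:  # make g0 best everywhere
            mads[ct][0] = 10.0
            evs[ct][0] = 10.0
        sel = rank_common(self._tables(mads, evs), 1)
        assert list(sel) == ["g0"]

    def test_worst_rank_scoring_and_tie_break(self):
        # 4 features; construct per-cell-type values so the 6 rank vectors
        # give max-rank scores {g0: 2, g1: 3, g2: 3, g3: 4} with g1 having
        # the smaller mean rank among the score-3 pair
        vals = {
            "monocyte": ([4.0, 3.0, 2.0, 1.0], [4.0, 3.0, 2.0, 1.0]),
            "neutrophil": ([3.0, 4.0, 2.0, 1.0], [3.0, 4.0, 2.0, 1.0]),
            "naive_T": ([3.0, 4.0, 2.0, 1.0], [4.0, 2.0, 3.0, 1.0]),
        }
        tables = self._tables(
            {ct: v[0] for ct, v in vals.items()}, {ct: v[1] for ct, v in vals.items()}
        )
        sel = list(rank_common(tables, 2))
        assert sel[0] == "g0"
        assert sel[1] == "g1"

    def test_monotone_transform_invariance(self, rng):
        mads = {ct: rng.random(50) for ct in CELLS}
        evs = {ct: rng.random(50) for ct in CELLS}
        base = list(rank_common(self._tables(mads, evs), 10))
        transformed = self._tables(mads, {ct: np.exp(3 * evs[ct]) for ct in CELLS})
        assert list(rank_common(transformed, 10)) == base

    def test_n_too_large_rejected(self, rng):
        tables = self._tables({ct: rng.random(5) for ct in CELLS}, {ct: rng.random(5) for ct in CELLS})
        with pytest.raises(ValueError, match="exceeds"):
            rank_common(tables, 6)


class TestSexDE:
    @staticmethod
    def _design(n_per_sex, cell_type="neutrophil"):
        rows = []
        for i in range(2 * n_per_sex):
            sex = "M" if i < n_per_sex else "F"
            rows.append((f"s{i}", f"D{i}", cell_type, sex, 40 + (i % 30), "2012-06-01"))
        return pd.DataFrame(
            rows, columns=["sample_id", "donor_id", "cell_type", "sex", "age", "collection_date"]
        )

    def test_injected_effect_detected(self, rng):
        from hypervar import CohortDesign

        design = CohortDesign(self._design(60))
        vals = rng.normal(5.0, 0.5, (200, 120))
        vals[0, :60] += 2.0  # logFC 2 in males
        expr = OmicsMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(200)], columns=[f"s{i}" for i in range(120)]),
            Scale.log2_expression,
        )
        de = sex_diff_expression(expr, design, "neutrophil", lfc_min=1.0)
        row = de.set_index("feature_id").loc["g0"]
        assert row["significant"]
        assert row["q"] < 0.05 and abs(row["logfc"]) >= 1
        assert not de.set_index("feature_id")["significant"].iloc[1:].any()

    def test_unmoderated_matches_classical_pooled_t(self, rng):
        from hypervar import CohortDesign

        design = CohortDesign(self._design(10))
        vals = rng.normal(size=(300, 20))
        expr = OmicsMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(300)], columns=[f"s{i}" for i in range(20)]),
            Scale.log2_expression,
        )
        de = sex_diff_expression(
            expr, design, "neutrophil", moderation=ModerationParams.none(18)
        )
        t_ref, p_ref = stats.ttest_ind(vals[:, :10], vals[:, 10:], axis=1)
        assert np.max(np.abs(de["t"].to_numpy() - t_ref)) < 1e-10
        assert np.max(np.abs(de["p"].to_numpy() - p_ref)) < 1e-10

    def test_single_sex_rejected(self):
        from hypervar import CohortDesign

        tab = self._design(6)
        tab["sex"] = "F"
        design = CohortDesign(tab)
        expr = OmicsMatrix(
            pd.DataFrame(np.zeros((5, 12)), index=[f"g{i}" for i in range(5)], columns=tab["sample_id"]),
            Scale.log2_expression,
        )
        with pytest.raises(ValueError, match="both sexes"):
            sex_diff_expression(expr, design, "neutrophil")
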