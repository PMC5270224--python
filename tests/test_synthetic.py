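import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy import stats

from hypervar import InjectedSet, SimConfig, simulate_cohort, simulate_traits, truth_eval
from hypervar.io import write_cohort
from hypervar.synthetic import simulate_weather

from conftest import gene_ids


class TestConfigValidation:
    def test_bad_maf_rejected(self):
        with pytest.raises(ValueError, match="MAF"):
            SimConfig(genetic_maf=0.7)

    def test_too_few_donors_rejected(self):
        with pytest.raises(ValueError, match="donors"):
            SimConfig(n_donors=3)

    def test_injected_ids_must_exist(self):
        with pytest.raises(ValueError, match="outside the feature range"):
            SimConfig(n_genes=10, injected_sets=(InjectedSet(["gene_99999"], "common"),))

    def test_inflation_below_one_rejected(self):
        with pytest.raises(ValueError, match="inflation"):
            InjectedSet(["gene_00000"], "common", 0.5)

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            SimConfig(injected_sets=(InjectedSet(["gene_00000"], "bogus:thing"),))


class TestCohortStructure:
    def test_every_donor_has_one_sample_per_cell_type(self, small_cohort):
        design = small_cohort.design
        counts = design.table.groupby(["donor_id", "cell_type"]).size()
        assert (counts == 1).all()
        for ct in small_cohort.config.cell_types:
            mat = small_cohort.expression[ct]
            assert list(mat.sample_ids) == list(design.samples(ct)["sample_id"])

    def test_truth_ids_within_feature_universe(self, small_cohort):
        genes = set(small_cohort.expression["monocyte"].feature_ids)
        cpgs = set(small_cohort.methylation["monocyte"].feature_ids)
        tr = small_cohort.truth
        assert set(tr.loc[tr["assay"] == "expression", "feature_id"]) <= genes
        assert set(tr.loc[tr["assay"] == "methylation", "feature_id"]) <= cpgs

    def test_no_effect_config_has_empty_truth(self, null_cohort):
        assert len(null_cohort.truth) == 0

    def test_methylation_is_bimodal(self, null_cohort):
        m = null_cohort.methylation["monocyte"].values.to_numpy().ravel()
        beta = 1 / (1 + 2.0 ** (-m))
        low, high = (beta < 0.3).mean(), (beta > 0.7).mean()
        assert low > 0.25 and high > 0.25


class TestDeterminism:
    def test_same_seed_reproduces_cohort(self):
        cfg = dict(n_donors=10, n_genes=60, n_cpgs=60, seed=99)
        a = simulate_cohort(SimConfig(**cfg))
        b = simulate_cohort(SimConfig(**cfg))
        for ct in a.config.cell_types:
            assert_frame_equal(a.expression[ct].values, b.expression[ct].values)
            assert_frame_equal(a.methylation[ct].values, b.methylation[ct].values)
        assert_frame_equal(a.design.table, b.design.table)
        assert_frame_equal(a.traits, b.traits)
        assert_frame_equal(a.truth, b.truth)

    def test_serialization_is_byte_identical(self, tmp_path):
        cfg = dict(n_donors=8, n_genes=40, n_cpgs=40, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(SimConfig(**cfg)), d1)
        write_cohort(simulate_cohort(SimConfig(**cfg)), d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimConfig(n_donors=8, n_genes=40, n_cpgs=10, seed=1))
        b = simulate_cohort(SimConfig(n_donors=8, n_genes=40, n_cpgs=10, seed=2))
        assert not np.allclose(
            a.expression["monocyte"].values, b.expression["monocyte"].values
        )


class TestVarianceArchitecture:
    def test_injected_variance_ratio_near_inflation(self):
        cfg = SimConfig(
            n_donors=125,
            n_genes=200,
            n_cpgs=10,
            seed=21,
            injected_sets=(InjectedSet(gene_ids(20), "specific:monocyte", 4.0),),
        )
        c = simulate_cohort(cfg)
        va = c.expression["monocyte"].values.iloc[:20].var(axis=1, ddof=1)
        vb = c.expression["neutrophil"].values.iloc[:20].var(axis=1, ddof=1)
        assert 3.0 <= (va / vb).mean() <= 5.0

    def test_null_variances_exchangeable_across_cell_types(self, null_cohort):
        va = null_cohort.expression["monocyte"].values.var(axis=1, ddof=1)
        vb = null_cohort.expression["neutrophil"].values.var(axis=1, ddof=1)
        ratio = (va / vb).to_numpy()
        assert 0.9 <= np.median(ratio) <= 1.1

    def test_mean_variance_trend_is_negative(self, null_cohort):
        vals = null_cohort.expression["naive_T"].values
        rho = stats.spearmanr(vals.mean(axis=1), vals.var(axis=1, ddof=1)).statistic
        assert rho < -0.3

    def test_genetic_features_inflate_via_mean_shifts(self):
        cfg = SimConfig(
            n_donors=125,
            n_genes=100,
            n_cpgs=10,
            seed=33,
            genetic_fraction=1.0,
            injected_sets=(InjectedSet(gene_ids(30), "specific:monocyte", 4.0),),
        )
        c = simulate_cohort(cfg)
        assert c.truth["genetic"].all()
        va = c.expression["monocyte"].values.iloc[:30].var(axis=1, ddof=1)
        vb = c.expression["neutrophil"].values.iloc[:30].var(axis=1, ddof=1)
        assert 2.5 <= (va / vb).mean() <= 6.0


class TestTraitsAndWeather:
    def test_target_rho_realized(self):
        cfg = SimConfig(
            n_donors=125,
            n_genes=100,
            n_cpgs=10,
            seed=17,
            trait_effect_features=(("gene_00000", "bmi", 0.6),),
        )
        c = simulate_cohort(cfg)
        expr = c.expression[cfg.cell_types[0]].values.loc["gene_00000"]
        donors = expr.index.str.split(":").str[0]
        rho = stats.spearmanr(
            expr.to_numpy(), c.traits["bmi"].reindex(donors).to_numpy()
        ).statistic
        assert abs(rho - 0.6) <= 0.15

    def test_null_rho_within_null_band(self):
        cfg = SimConfig(n_donors=125, n_genes=100, n_cpgs=10, seed=27)
        c = simulate_cohort(cfg)
        expr = c.expression[cfg.cell_types[0]].values.loc["gene_00000"]
        donors = expr.index.str.split(":").str[0]
        rho = stats.spearmanr(
            expr.to_numpy(), c.traits["bmi"].reindex(donors).to_numpy()
        ).statistic
        assert abs(rho) <= 1.96 / np.sqrt(125 - 1)

    def test_unknown_trait_rejected(self, null_cohort):
        cfg = SimConfig(trait_effect_features=(("gene_00000", "shoe_size", 0.5),))
        with pytest.raises(ValueError, match="unknown trait"):
            simulate_traits(null_cohort.design, cfg, null_cohort.expression)

    def test_weather_gaps_follow_config(self):
        none = simulate_weather(SimConfig(weather_missing_fraction=0.0, seed=1))
        assert not none[["tmin", "tmax"]].isna().any().any()
        some = simulate_weather(SimConfig(weather_missing_fraction=0.2, seed=1))
        assert some["tmin"].isna().mean() == pytest.approx(0.2, abs=0.05)

    def test_sex_effect_realized(self, small_cohort):
        expr = small_cohort.expression["monocyte"].values.loc["gene_00050"]
        donors = expr.index.str.split(":").str[0]
        sex = small_cohort.design.donor_attr("sex").reindex(donors)
        diff = expr[(sex == "M").to_numpy()].mean() - expr[(sex == "F").to_numpy()].mean()
        assert diff == pytest.approx(2.0, abs=0.6)


class TestTruthEval:
    @staticmethod
    def _truth(n, label="specific:neutrophil"):
        return pd.DataFrame(
            {
                "feature_id": gene_ids(n),
                "assay": "expression",
                "label": label,
                "variance_inflation": 4.0,
                "genetic": False,
                "maf": np.nan,
            }
        )

    def test_perfect_classification(self):
        truth = self._truth(10)
        cls = truth[["feature_id", "label"]]
        m = truth_eval(cls, truth).set_index("label").loc["overall"]
        assert m["sensitivity"] == 1.0 and m["precision"] == 1.0 and m["label_accuracy"] == 1.0

    def test_empty_classification(self):
        truth = self._truth(10)
        cls = pd.DataFrame({"feature_id": gene_ids(10), "label": "none"})
        m = truth_eval(cls, truth).set_index("label").loc["overall"]
        assert m["sensitivity"] == 0.0

    def test_hand_arithmetic(self):
        truth = self._truth(100)
        labels = ["specific:neutrophil"] * 80 + ["none"] * 20
        cls = pd.DataFrame({"feature_id": gene_ids(120), "label": labels + ["none"] * 15 + ["specific:neutrophil"] * 5})
        m = truth_eval(cls, truth).set_index("label").loc["overall"]
        assert m["sensitivity"] == pytest.approx(0.80)
        assert m["precision"] == pytest.approx(80 / 85)

    def test_common_scored_against_rank_list(self):
        truth = self._truth(10, label="common")
        cls = pd.DataFrame({"feature_id": gene_ids(20), "label": "none"})
        m = truth_eval(cls, truth, common_list=gene_ids(8)).set_index("label")
        assert m.loc["common", "sensitivity"] == pytest.approx(0.8)
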