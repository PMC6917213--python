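"""Feature construction, univariate screening, the survival forest,
forward selection and risk stratification."""

import numpy as np
import pandas as pd
import pytest

from angiosig import rsf, syndata
from angiosig.errors import ConfigurationError, EstimationError, InputError
from angiosig.rsf import ForestConfig
from angiosig.survcore import StepFunction

from conftest import simulate_surv


def _cohort(n=400, n_genes=10, prog=(), seed=0, **kw):
    genes = tuple(f"HGENE{i:04d}" for i in range(n_genes))
    cfg = syndata.CohortSimConfig(
        n_patients=n, n_genes=n_genes, genes=genes,
        prognostic_genes=tuple((genes[i], b) for i, b in prog),
        train_fraction=0.999, seed=seed, **kw,
    )
    train, _, _ = syndata.gen_cohort(cfg)
    return train, list(genes)


class TestBuildFeatures:
    def test_feature_count_is_two_per_gene_plus_clinical(self):
        train, genes = _cohort(n=120, n_genes=20)
        feats, _ = rsf.build_features(train.expr, train.clinical, genes)
        assert feats.shape[1] == 2 * 20 + 2
        assert set(feats.columns) >= {"age", "stage"}
        assert feats.filter(like="_D").isin([0.0, 1.0]).all(axis=None)

    def test_constant_gene_binary_copy_is_all_zero(self):
        expr = pd.DataFrame(
            {"p1": [1.0, 0.2], "p2": [1.0, 0.7], "p3": [1.0, 0.1]},
            index=["gC", "gV"],
        )
        clin = pd.DataFrame(
            {"age": [50.0, 60, 70], "stage": [1.0, 2, 2]},
            index=["p1", "p2", "p3"],
        )
        feats, _ = rsf.build_features(expr, clin, ["gC", "gV"])
        assert (feats["gC_D"] == 0).all()

    def test_odd_n_distinct_values_give_half_ones(self):
        n = 11
        expr = pd.DataFrame([np.arange(n, dtype=float)], index=["g"],
                            columns=[f"p{i}" for i in range(n)])
        clin = pd.DataFrame({"age": 50.0, "stage": 1.0}, index=expr.columns)
        feats, _ = rsf.build_features(expr, clin, ["g"])
        assert feats["g_D"].sum() == (n - 1) / 2

    def test_training_medians_reused_on_new_patients(self):
        train, genes = _cohort(n=100, n_genes=3, seed=1)
        _, info = rsf.build_features(train.expr, train.clinical, genes)
        other, _ = _cohort(n=50, n_genes=3, seed=2)
        feats, _ = rsf.build_features(other.expr, other.clinical, genes, info=info)
        manual = (other.expr.loc[genes].gt(info.medians, axis=0)).T.astype(float)
        np.testing.assert_allclose(feats[[f"{g}_D" for g in genes]], manual)

    def test_missing_stage_imputed_with_median(self):
        train, genes = _cohort(n=200, n_genes=2, seed=3, stage_missing=0.3)
        feats, info = rsf.build_features(train.expr, train.clinical, genes)
        assert feats["stage"].notna().all()
        assert len(info.stage_filled) > 0
        filled = feats.loc[list(info.stage_filled), "stage"]
        assert (filled == info.stage_fill).all()

    def test_absent_gene_rejected_by_name(self):
        train, genes = _cohort(n=50, n_genes=2)
        with pytest.raises(InputError, match="nope"):
            rsf.build_features(train.expr, train.clinical, ["nope"])


class TestUnivariateFilter:
    def test_planted_gene_ranks_first(self):
        train, genes = _cohort(n=1000, n_genes=50, prog=((7, 1.0),), seed=5)
        feats, _ = rsf.build_features(train.expr, train.clinical, genes)
        ranked = rsf.univariate_filter(feats, train.time, train.event)
        assert ranked["feature"].iloc[0] == genes[7]

    def test_noise_features_retained_near_alpha(self):
        train, genes = _cohort(n=300, n_genes=100, seed=6,
                               age_effect=0.0, stage_effect=0.0)
        feats, _ = rsf.build_features(train.expr, train.clinical, genes)
        cont_only = feats[genes]  # independent columns for a clean rate
        ranked = rsf.univariate_filter(cont_only, train.time, train.event,
                                       always_keep=())
        assert 0.0 <= len(ranked) / 100 <= 0.12

    def test_alpha_one_keeps_everything_ranked(self):
        train, genes = _cohort(n=150, n_genes=5, seed=7)
        feats, _ = rsf.build_features(train.expr, train.clinical, genes)
        ranked = rsf.univariate_filter(feats, train.time, train.event, alpha=1.0)
        ps = ranked["p"].to_numpy()
        assert (np.diff(ps[np.isfinite(ps)]) >= 0).all()
        assert len(ranked) >= 10

    def test_clinical_always_offered(self):
        train, genes = _cohort(n=200, n_genes=3, seed=8,
                               age_effect=0.0, stage_effect=0.0)
        feats, _ = rsf.build_features(train.expr, train.clinical, genes)
        ranked = rsf.univariate_filter(feats, train.time, train.event, alpha=1e-9)
        assert {"age", "stage"} <= set(ranked["feature"])


@pytest.fixture(scope="module")
def strong_cohort():
    genes = tuple(f"HGENE{i:04d}" for i in range(6))
    cfg = syndata.CohortSimConfig(
        n_patients=700, n_genes=6, genes=genes,
        prognostic_genes=((genes[0], 1.0), (genes[1], 0.8)),
        train_fraction=0.6, seed=17,
    )
    train, valid, _ = syndata.gen_cohort(cfg)
    f_train, info = rsf.build_features(train.expr, train.clinical, list(genes))
    f_valid, _ = rsf.build_features(valid.expr, valid.clinical, list(genes), info=info)
    return train, valid, f_train, f_valid


class TestGrowForest:
    def test_same_seed_reproduces_forest_exactly(self, strong_cohort):
        train, _, f_train, f_valid = strong_cohort
        cfg = ForestConfig(ntree=30, n_split=5)
        a = rsf.grow_forest(f_train, train.time, train.event, config=cfg, seed=9)
        b = rsf.grow_forest(f_train, train.time, train.event, config=cfg, seed=9)
        assert a.oob_error_ == b.oob_error_
        np.testing.assert_array_equal(a.predict_chf(f_valid), b.predict_chf(f_valid))

    def test_single_strong_feature_beats_oob_threshold(self):
        x, t, e = simulate_surv(np.random.default_rng(3), 1000, beta=1.0)
        feats = pd.DataFrame({"x": x, "noise": np.random.default_rng(4).standard_normal(1000)})
        forest = rsf.grow_forest(feats, t, e, config=ForestConfig(ntree=100, mtry=1),
                                 seed=2)
        assert forest.oob_error_ < 0.35

    def test_pure_noise_oob_near_half(self, rng):
        _, t, e = simulate_surv(rng, 400)
        feats = pd.DataFrame(rng.standard_normal((400, 20)),
                             columns=[f"n{i}" for i in range(20)])
        forest = rsf.grow_forest(feats, t, e, config=ForestConfig(ntree=100), seed=5)
        assert abs(forest.oob_error_ - 0.5) < 0.05

    def test_zero_events_rejected(self, rng):
        feats = pd.DataFrame({"x": rng.standard_normal(50)})
        with pytest.raises(InputError):
            rsf.grow_forest(feats, np.ones(50), np.zeros(50, int))

    def test_predicted_survival_monotone_and_bounded(self, strong_cohort):
        train, _, f_train, f_valid = strong_cohort
        forest = rsf.grow_forest(f_train, train.time, train.event,
                                 config=ForestConfig(ntree=40), seed=6)
        for s in forest.predict_survival(f_valid.iloc[:20]):
            vals = s(forest.grid)
            assert (np.diff(vals) <= 1e-12).all()
            assert vals.min() >= 0 and vals.max() <= 1

    def test_risk_profiles_ordered(self, strong_cohort):
        train, _, f_train, _ = strong_cohort
        forest = rsf.grow_forest(f_train, train.time, train.event,
                                 config=ForestConfig(ntree=60), seed=7)
        hi = f_train.iloc[[0]].copy()
        lo = f_train.iloc[[0]].copy()
        hi[["HGENE0000", "HGENE0001"]] = 2.0
        hi[["HGENE0000_D", "HGENE0001_D"]] = 1.0
        lo[["HGENE0000", "HGENE0001"]] = -2.0
        lo[["HGENE0000_D", "HGENE0001_D"]] = 0.0
        s_hi = forest.predict_survival(hi)[0]
        s_lo = forest.predict_survival(lo)[0]
        assert s_hi(10.0) < s_lo(10.0)

    def test_unused_feature_values_do_not_change_predictions(self, strong_cohort):
        train, _, f_train, f_valid = strong_cohort
        feats = f_train.copy()
        feats["inert"] = 0.0  # constant -> never splittable
        forest = rsf.grow_forest(feats, train.time, train.event,
                                 config=ForestConfig(ntree=30), seed=8)
        fv = f_valid.copy()
        fv["inert"] = 0.0
        base = forest.predict_chf(fv)
        fv["inert"] = 99.0
        np.testing.assert_array_equal(base, forest.predict_chf(fv))

    def test_schema_mismatch_rejected(self, strong_cohort):
        train, _, f_train, f_valid = strong_cohort
        forest = rsf.grow_forest(f_train, train.time, train.event,
                                 config=ForestConfig(ntree=10), seed=1)
        with pytest.raises(InputError):
            forest.predict_chf(f_valid.iloc[:, :3])

    def test_json_round_trip_preserves_predictions(self, strong_cohort, tmp_path):
        train, _, f_train, f_valid = strong_cohort
        forest = rsf.grow_forest(f_train, train.time, train.event,
                                 config=ForestConfig(ntree=15), seed=4)
        path = tmp_path / "model.json"
        forest.save(path)
        back = rsf.SurvivalForest.load(path)
        np.testing.assert_allclose(back.predict_chf(f_valid),
                                   forest.predict_chf(f_valid), atol=1e-12)
        assert back.feature_names == forest.feature_names


class TestForwardSelect:
    def test_single_candidate_gives_size_one_model(self, strong_cohort):
        train, _, f_train, _ = strong_cohort
        res = rsf.forward_select(["HGENE0000"], f_train, train.time, train.event,
                                 config=ForestConfig(ntree=30), seed=3)
        assert res.chosen == ("HGENE0000",)
        assert len(res.trace) == 1

    def test_chosen_k_is_argmin_of_trace(self, strong_cohort):
        train, _, f_train, _ = strong_cohort
        ranked = ["HGENE0000", "HGENE0001", "HGENE0002", "HGENE0003"]
        res = rsf.forward_select(ranked, f_train, train.time, train.event,
                                 config=ForestConfig(ntree=40, n_split=5), seed=11)
        errs = res.trace["oob_error"].to_numpy()
        assert len(res.chosen) == int(np.argmin(errs)) + 1

    def test_chosen_model_beats_size_one_with_two_informative(self, strong_cohort):
        train, _, f_train, _ = strong_cohort
        ranked = ["HGENE0000", "HGENE0001", "HGENE0002"]
        res = rsf.forward_select(ranked, f_train, train.time, train.event,
                                 config=ForestConfig(ntree=60, n_split=5), seed=13)
        size_one = res.trace["oob_error"].iloc[0]
        assert res.forest.oob_error_ <= size_one

    def test_empty_ranked_list_rejected(self, strong_cohort):
        train, _, f_train, _ = strong_cohort
        with pytest.raises(InputError):
            rsf.forward_select([], f_train, train.time, train.event)


class TestStratifyRisk:
    @staticmethod
    def _sf(points):
        ts, vs = zip(*points)
        return StepFunction(np.array(ts), np.array(vs), y_before=1.0)

    @pytest.mark.parametrize(
        "s15, s75, expected",
        [(0.9, 0.95, "low"), (0.4, 0.6, "intermediate"), (0.2, 0.3, "high")],
    )
    def test_sequential_rule(self, s15, s75, expected):
        sf = self._sf([(7.5, s75), (15.0, s15)])
        call = rsf.stratify_risk(sf)
        assert call.risk_class == expected
        assert call.s_long == pytest.approx(s15)
        assert call.s_short == pytest.approx(s75)

    def test_bad_horizon_order_rejected(self):
        sf = self._sf([(7.5, 0.9), (15.0, 0.8)])
        with pytest.raises(ConfigurationError):
            rsf.stratify_risk(sf, horizons=(7.5, 15.0))

    def test_cohort_stratification_partitions_patients(self, strong_cohort):
        train, valid, f_train, f_valid = strong_cohort
        forest = rsf.grow_forest(f_train, train.time, train.event,
                                 config=ForestConfig(ntree=60), seed=19)
        calls = rsf.stratify_cohort(forest, f_valid)
        assert calls["risk_class"].isin(rsf.RISK_CLASSES).all()
        assert len(calls) == len(valid.patients)
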