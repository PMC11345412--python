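"""Two-stage offset model: stage-1 MLE, elastic-net stage 2 against
statsmodels, CV hyperparameter selection, importance, bootstrap stability,
and frozen-weight transfer."""

import numpy as np
import pandas as pd
import pytest

from grm import SimulationConfig, apply_model, bootstrap_stability, \
    fit_stage1, fit_stage2, importance, simulate_genotypes, \
    simulate_phenotype, stratified_folds
from grm.models import ModelError, TransferError, _EnetPath, _sigmoid
from grm.evaluate import auroc


def _sim(n=1500, effects=((0, 0.9),), seed=50, n_blocks=4, spb=3):
    cfg = SimulationConfig(n_samples=n, n_blocks=n_blocks, snps_per_block=spb,
                           block_r2=0.2, causal_snps=list(effects),
                           prevalence=0.25, seed=seed)
    g = simulate_genotypes(cfg)
    truth = simulate_phenotype(g, cfg, seed + 1)
    X = pd.DataFrame(g.dosages, columns=g.variant_ids)
    cov = pd.DataFrame({"age": truth.age, "sex": truth.sex})
    return cfg, g, truth, X, cov


class TestStage1:
    def test_intercept_only_offset_is_logit_of_case_fraction(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        cov = pd.DataFrame({"z": np.zeros(10)})
        off = fit_stage1(y, cov)
        expected = np.log(0.2 / 0.8)
        np.testing.assert_allclose(off.offset, expected, atol=1e-6)

    def test_balanced_classes_give_zero_offset(self):
        y = np.array([0, 1] * 20)
        off = fit_stage1(y, pd.DataFrame(index=range(40)))
        np.testing.assert_allclose(off.offset, 0.0, atol=1e-8)

    def test_recovers_planted_demographic_betas_within_3se(self):
        cfg, g, truth, X, cov = _sim(n=5000, effects=(), seed=51,
                                     n_blocks=2, spb=2)
        import statsmodels.api as sm
        off = fit_stage1(truth.true_case_labels, cov)
        res = sm.Logit(truth.true_case_labels,
                       sm.add_constant(cov.to_numpy())).fit(disp=0)
        b_age, b_sex = cfg.demographic_effects
        # centered-age generation shifts only the intercept
        for j, true_b in ((1, b_age), (2, b_sex)):
            assert abs(res.params[j] - true_b) <= 3 * res.bse[j]
            assert off.stage1_coefficients[cov.columns[j - 1]] == \
                pytest.approx(res.params[j], abs=1e-6)

    def test_perfect_separation_capped_and_flagged(self):
        y = np.array([0] * 10 + [1] * 10)
        cov = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
        with pytest.warns(UserWarning, match="separation"):
            off = fit_stage1(y, cov)
        assert off.separation_flagged
        assert max(abs(v) for v in off.stage1_coefficients.values()) <= 15.0

    def test_requires_both_classes(self):
        with pytest.raises(ModelError):
            fit_stage1(np.ones(5), pd.DataFrame({"x": np.zeros(5)}))


class TestElasticNetSolver:
    def test_matches_statsmodels_on_standardized_features(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(0)
        n, p = 400, 8
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        off = rng.normal(scale=0.5, size=n)
        beta = np.array([1.0, -0.5, 0, 0, 0.8, 0, 0, 0])
        y = (rng.random(n) < _sigmoid(0.3 + X @ beta + off)).astype(float)
        lam, mix = 0.05, 0.5
        path = _EnetPath(X, y, off)
        b0s, bs = path.fit(mix, np.geomspace(path.lambda_max(mix), lam, 30))
        res = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial(),
                     offset=off).fit_regularized(
            method="elastic_net", alpha=lam * np.r_[0, np.ones(p)],
            L1_wt=mix, maxiter=2000, cnvrg_tol=1e-10)
        np.testing.assert_allclose(np.r_[b0s[-1], bs[-1]], res.params,
                                   atol=1e-6)

    def test_huge_lambda_reproduces_stage1_predictions(self):
        cfg, g, truth, X, cov = _sim(seed=52)
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        path = _EnetPath(X.to_numpy(float), y.astype(float), s1.offset)
        b0s, bs = path.fit(0.5, np.array([1e3]))
        assert np.all(bs[0] == 0.0)
        np.testing.assert_allclose(_sigmoid(b0s[0] + s1.offset),
                                   _sigmoid(s1.offset), atol=1e-6)


class TestStage2:
    def test_planted_snp_selected_across_seeds(self):
        for seed in range(5):
            cfg, g, truth, X, cov = _sim(n=1200, effects=((0, 0.9),),
                                         seed=60 + seed)
            y = truth.true_case_labels
            s1 = fit_stage1(y, cov)
            m = fit_stage2(y, X, s1, alpha_grid=(0.5,), n_lambda=30,
                           seed=seed)
            assert m.coefficients[g.variant_ids[0]] != 0.0

    def test_chosen_hyperparams_maximize_cv_objective(self):
        cfg, g, truth, X, cov = _sim(n=800, seed=53)
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        m = fit_stage2(y, X, s1, alpha_grid=(0.2, 0.6, 1.0), n_lambda=20,
                       seed=3)
        cv = m.cv_results
        best = cv.loc[cv.mean_deviance.idxmin()]
        assert m.alpha == best["alpha"]
        assert m.lambda_ == pytest.approx(best["lambda"])
        assert m.alpha in (0.2, 0.6, 1.0)
        # independent re-evaluation of the chosen cell with the same folds
        fold = stratified_folds(y, 5, 3)
        np.testing.assert_array_equal(fold, m.cv_fold)
        dev = 0.0
        Xv = X.to_numpy(float)
        for f in range(5):
            tr, te = fold != f, fold == f
            p_tr = _EnetPath(Xv[tr], y[tr].astype(float), s1.offset[tr])
            lambdas = _EnetPath(Xv, y.astype(float), s1.offset).lambdas(
                m.alpha, 20, 1e-3)
            b0s, bs = p_tr.fit(m.alpha, lambdas)
            i = int(np.argmin(np.abs(lambdas - m.lambda_)))
            pr = np.clip(_sigmoid(b0s[i] + Xv[te] @ bs[i] + s1.offset[te]),
                         1e-12, 1 - 1e-12)
            dev += float(-2 * np.mean(y[te] * np.log(pr)
                                      + (1 - y[te]) * np.log(1 - pr)))
        assert dev / 5 == pytest.approx(best["mean_deviance"], rel=1e-8)

    def test_offset_contract_zero_genetics_reproduce_stage1(self):
        cfg, g, truth, X, cov = _sim(n=600, seed=54)
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        m = fit_stage2(y, X, s1, alpha_grid=(0.5,), n_lambda=10, seed=0)
        for name in m.feature_names:
            m.coefficients[name] = 0.0
        m.coefficients["intercept"] = 0.0
        np.testing.assert_allclose(m.predict_proba(X, s1.offset),
                                   _sigmoid(s1.offset))

    def test_deterministic_under_seed(self):
        cfg, g, truth, X, cov = _sim(n=500, seed=55)
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        m1 = fit_stage2(y, X, s1, alpha_grid=(0.3, 0.9), n_lambda=15, seed=9)
        m2 = fit_stage2(y, X, s1, alpha_grid=(0.3, 0.9), n_lambda=15, seed=9)
        assert m1.coefficients == m2.coefficients
        np.testing.assert_array_equal(m1.cv_predictions, m2.cv_predictions)

    def test_constant_columns_dropped_with_warning(self):
        cfg, g, truth, X, cov = _sim(n=400, seed=56)
        X = X.copy()
        X["constant"] = 1.0
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        with pytest.warns(UserWarning, match="constant"):
            m = fit_stage2(y, X, s1, alpha_grid=(0.5,), n_lambda=10, seed=0)
        assert "constant" not in m.feature_names

    def test_nonfinite_features_rejected(self):
        cfg, g, truth, X, cov = _sim(n=300, seed=57)
        X = X.copy()
        X.iloc[0, 0] = np.nan
        s1 = fit_stage1(truth.true_case_labels, cov)
        with pytest.raises(ModelError):
            fit_stage2(truth.true_case_labels, X, s1)

    def test_stratified_folds_balance_cases(self):
        y = np.r_[np.ones(20), np.zeros(80)]
        fold = stratified_folds(y, 5, seed=1)
        for f in range(5):
            assert y[fold == f].sum() == 4


class TestImportance:
    def _fit(self, seed=58):
        cfg, g, truth, X, cov = _sim(n=800, effects=((0, 0.8), (3, 0.6)),
                                     seed=seed, n_blocks=4, spb=1)
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        m = fit_stage2(y, X, s1, predictor_set="multi_prs", penalize=False,
                       seed=0)
        return m, X

    def test_single_nonzero_coefficient_gets_importance_one(self):
        m, X = self._fit()
        m.coefficients = {"intercept": 0.1, **{n: 0.0 for n in m.feature_names}}
        m.coefficients[m.feature_names[0]] = 0.5
        sds = {n: 1.0 for n in m.feature_names}
        assert importance(m, sds) == {m.feature_names[0]: 1.0}

    def test_equal_beta_sd_products_split_evenly(self):
        m, X = self._fit()
        m.coefficients = {"intercept": 0.0,
                          **{n: 0.0 for n in m.feature_names}}
        m.coefficients[m.feature_names[0]] = 0.5
        m.coefficients[m.feature_names[1]] = -1.0
        sds = {m.feature_names[0]: 2.0, m.feature_names[1]: 1.0}
        sds.update({n: 1.0 for n in m.feature_names[2:]})
        imp = importance(m, sds)
        assert imp[m.feature_names[0]] == pytest.approx(0.5)
        assert imp[m.feature_names[1]] == pytest.approx(0.5)

    def test_feature_rescaling_leaves_importance_invariant(self):
        cfg, g, truth, X, cov = _sim(n=1000, effects=((0, 0.8),), seed=59,
                                     n_blocks=3, spb=1)
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        m1 = fit_stage2(y, X, s1, penalize=False, seed=0)
        X2 = X.copy()
        X2.iloc[:, 0] = X2.iloc[:, 0] * 2.0
        m2 = fit_stage2(y, X2, s1, penalize=False, seed=0)
        sds1 = {n: X[n].std(ddof=0) for n in X}
        sds2 = {n: X2[n].std(ddof=0) for n in X2}
        i1, i2 = importance(m1, sds1), importance(m2, sds2)
        for n in i1:
            assert i1[n] == pytest.approx(i2[n], rel=1e-5)

    def test_all_zero_coefficients_give_empty_importance(self):
        m, X = self._fit()
        m.coefficients = {n: 0.0 for n in ["intercept"] + m.feature_names}
        assert importance(m, {n: 1.0 for n in m.feature_names}) == {}


class TestBootstrap:
    def test_single_resample_has_binary_frequencies(self):
        cfg, g, truth, X, cov = _sim(n=400, seed=61)
        rep = bootstrap_stability(truth.true_case_labels, X, cov, n_boot=1,
                                  seed=0, n_lambda=10, n_folds=3)
        assert set(rep.table.selection_frequency.unique()) <= {0.0, 1.0}

    def test_huge_effect_feature_always_retained(self):
        cfg, g, truth, X, cov = _sim(n=900, effects=((0, 1.2),), seed=62,
                                     n_blocks=4, spb=1)
        rep = bootstrap_stability(truth.true_case_labels, X, cov, n_boot=30,
                                  seed=1, n_lambda=15, n_folds=3)
        row = rep.table.set_index("feature").loc[g.variant_ids[0]]
        assert row.selection_frequency == 1.0 and row.retained

    def test_retained_importances_sum_to_one(self):
        cfg, g, truth, X, cov = _sim(n=900, effects=((0, 1.2), (3, 1.0)),
                                     seed=63, n_blocks=4, spb=1)
        rep = bootstrap_stability(truth.true_case_labels, X, cov, n_boot=25,
                                  seed=2, n_lambda=15, n_folds=3)
        t = rep.table
        assert (t.retained == (t.selection_frequency >= 0.95)).all()
        if t.retained.any():
            assert t.loc[t.retained, "importance"].sum() == pytest.approx(1.0)
            assert (t.importance >= 0).all()

    def test_invalid_arguments_rejected(self):
        cfg, g, truth, X, cov = _sim(n=300, seed=64)
        with pytest.raises(ModelError):
            bootstrap_stability(truth.true_case_labels, X, cov, n_boot=0)
        with pytest.raises(ModelError):
            bootstrap_stability(truth.true_case_labels, X, cov, n_boot=5,
                                refit_hyperparams="none")


class TestTransfer:
    def test_identity_transfer_reproduces_training_predictions(self):
        cfg, g, truth, X, cov = _sim(n=700, effects=((0, 0.8),), seed=65)
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        m = fit_stage2(y, X, s1, alpha_grid=(0.5,), n_lambda=15, seed=0)
        probs, s1b = apply_model(m, y, cov, X)
        np.testing.assert_allclose(probs, m.predict_proba(X, s1.offset),
                                   atol=1e-8)

    def test_null_genetics_reduce_to_new_stage1(self):
        cfg, g, truth, X, cov = _sim(n=500, seed=66)
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        m = fit_stage2(y, X, s1, alpha_grid=(0.5,), n_lambda=10, seed=0)
        for n in m.feature_names:
            m.coefficients[n] = 0.0
        m.coefficients["intercept"] = 0.0
        cfg2, g2, truth2, X2, cov2 = _sim(n=500, seed=67)
        probs, s1_new = apply_model(m, truth2.true_case_labels, cov2, X2)
        np.testing.assert_allclose(probs, _sigmoid(s1_new.offset))

    def test_missing_feature_raises_transfer_error(self):
        cfg, g, truth, X, cov = _sim(n=500, effects=((0, 1.0),), seed=68)
        y = truth.true_case_labels
        s1 = fit_stage1(y, cov)
        m = fit_stage2(y, X, s1, alpha_grid=(1.0,), n_lambda=15, seed=0)
        assert m.nonzero_features
        X2 = X.drop(columns=[m.nonzero_features[0]])
        with pytest.raises(TransferError):
            apply_model(m, y, cov, X2)

    def test_transferred_elasticnet_beats_transferred_apoe_on_auroc(self):
        """Frozen elastic-net weights discriminate better than the APOE-only
        model on a fresh cohort from the same generative process."""
        wins = 0
        for seed in range(5):
            cfg = SimulationConfig(n_samples=1200, n_blocks=4,
                                   snps_per_block=3, block_r2=0.2,
                                   causal_snps=[(0, 0.7), (6, 0.6)],
                                   prevalence=0.25, seed=70 + seed,
                                   include_apoe=True, apoe_effect=0.8)
            g = simulate_genotypes(cfg)
            truth = simulate_phenotype(g, cfg, 170 + seed)
            y = truth.true_case_labels
            cov = pd.DataFrame({"age": truth.age, "sex": truth.sex})
            X = pd.DataFrame(g.dosages, columns=g.variant_ids)
            from grm import apoe_e4_count
            Xa = pd.DataFrame({"apoe_e4": apoe_e4_count(g).counts.astype(float)})
            s1 = fit_stage1(y, cov)
            men = fit_stage2(y, X, s1, alpha_grid=(0.5,), n_lambda=20, seed=0)
            mapo = fit_stage2(y, Xa, s1, predictor_set="apoe", seed=0)
            g2 = simulate_genotypes(cfg, seed=9000 + seed)
            truth2 = simulate_phenotype(g2, cfg, 9100 + seed)
            y2 = truth2.true_case_labels
            cov2 = pd.DataFrame({"age": truth2.age, "sex": truth2.sex})
            X2 = pd.DataFrame(g2.dosages, columns=g2.variant_ids)
            Xa2 = pd.DataFrame({"apoe_e4": apoe_e4_count(g2).counts.astype(float)})
            p_en, _ = apply_model(men, y2, cov2, X2)
            p_ap, _ = apply_model(mapo, y2, cov2, Xa2)
            wins += auroc(p_en, y2) > auroc(p_ap, y2)
        assert wins >= 4
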