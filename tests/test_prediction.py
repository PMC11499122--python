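"""Nested-CV LASSO, ROC arithmetic, confusion counts, odds-titer link."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import vaxresp as v
from vaxresp.prediction import _fit_l1_logistic


def _toy_data(n=60, p=8, signal=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    logits = signal * X[:, 0] - signal * X[:, 1]
    y = (logits + rng.logistic(0, 1, n) > 0).astype(int)
    return pd.DataFrame(X, columns=[f"g{i}" for i in range(p)]), y


class TestNestedLasso:
    def test_huge_penalty_gives_prevalence_probabilities(self):
        X, y = _toy_data()
        n = len(y)
        model = _fit_l1_logistic(X.to_numpy(), y, lam=1e3)
        assert np.all(model.coef_ == 0.0)
        probs = model.predict_proba(X.to_numpy())[:, 1]
        assert np.allclose(probs, probs[0])
        assert probs[0] == pytest.approx(y.mean(), abs=0.02)

    def test_one_dimensional_penalized_likelihood_oracle(self):
        """Single-feature fit agrees with a direct grid/scalar optimization
        of the L1-penalized logistic likelihood: same sign, shrunk size."""
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(0, 1, n)
        y = (1.2 * x + rng.logistic(0, 1, n) > 0).astype(int)
        lam = 0.05
        model = _fit_l1_logistic(x[:, None], y, lam)
        b_pen = model.coef_[0, 0]

        def nll(params, penalty):
            b0, b = params
            z = b0 + b * x
            return np.logaddexp(0, -z * (2 * y - 1)).mean() + penalty * abs(b)

        oracle = optimize.minimize(nll, [0.0, 0.5], args=(lam,), method="Nelder-Mead",
                                   options={"xatol": 1e-8, "fatol": 1e-12})
        b_oracle = oracle.x[1]
        unpen = optimize.minimize(nll, [0.0, 0.5], args=(0.0,), method="Nelder-Mead").x[1]
        assert b_pen == pytest.approx(b_oracle, abs=2e-2)
        assert np.sign(b_pen) == np.sign(unpen)
        assert abs(b_pen) < abs(unpen)

    def test_heldout_probabilities_come_from_other_folds(self):
        X, y = _toy_data(n=80)
        est = v.NestedLassoLogisticCV(k_folds=4, inner_folds=3,
                                      n_lambdas=10, random_state=0).fit(X, y)
        assert np.isfinite(est.heldout_proba_).all()
        assert set(est.fold_assignments_) == {0, 1, 2, 3}
        # fold labels are stratified: every fold holds both classes
        for f in range(4):
            assert len(set(y[est.fold_assignments_ == f])) == 2

    def test_selected_features_have_nonzero_coefs_only(self):
        X, y = _toy_data(n=100)
        est = v.NestedLassoLogisticCV(k_folds=4, inner_folds=3, n_lambdas=10,
                                      random_state=1).fit(X, y)
        nz = {n for n, c in zip(est.feature_names_, est.coef_) if c != 0}
        assert set(est.selected_features_) == nz

    def test_fold_standardization_differs_from_leaked_global(self):
        """On features with wildly unbalanced scales, z-scoring on all data
        (leak) changes the held-out probabilities relative to honest
        training-fold-only standardization."""
        rng = np.random.default_rng(5)
        n = 60
        X = pd.DataFrame({
            "big": np.r_[rng.normal(0, 1000, n // 2), rng.normal(3000, 1000, n // 2)],
            "small": rng.normal(0, 1e-3, n),
        })
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        honest = v.NestedLassoLogisticCV(k_folds=3, inner_folds=3, n_lambdas=8,
                                         standardize="fold", random_state=2)
        leaky = v.NestedLassoLogisticCV(k_folds=3, inner_folds=3, n_lambdas=8,
                                        standardize="global", random_state=2)
        p_h = honest.fit(X, y).heldout_proba_
        p_l = leaky.fit(X, y).heldout_proba_
        assert np.abs(p_h - p_l).max() > 1e-6

    def test_permuted_labels_destroy_heldout_auroc(self):
        X, y = _toy_data(n=90, signal=3.0, seed=7)
        rng = np.random.default_rng(8)
        aurocs = []
        for _ in range(5):
            yp = rng.permutation(y)
            est = v.NestedLassoLogisticCV(k_folds=3, inner_folds=3,
                                          n_lambdas=8, random_state=3).fit(X, yp)
            aurocs.append(v.roc_auc(est.heldout_proba_, yp).auroc)
        assert abs(np.mean(aurocs) - 0.5) < 0.12

    def test_single_class_or_tiny_minority_raises(self):
        X, _ = _toy_data(n=20)
        with pytest.raises(ValueError):
            v.NestedLassoLogisticCV().fit(X, np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="minority"):
            v.NestedLassoLogisticCV(k_folds=5).fit(
                X, np.r_[np.ones(2), np.zeros(18)].astype(int))


class TestRocAuc:
    def test_perfect_separation(self):
        roc = v.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auroc == 1.0

    def test_all_ties_give_half(self):
        roc = v.roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0])
        assert roc.auroc == 0.5

    def test_hand_example_three_quarters(self):
        roc = v.roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0])
        assert roc.auroc == pytest.approx(0.75)

    def test_matches_pairwise_concordance_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            p = rng.choice(np.linspace(0, 1, 11), n)  # force ties
            pos, neg = p[y == 1], p[y == 0]
            conc = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
            want = conc / (len(pos) * len(neg))
            assert v.roc_auc(p, y).auroc == pytest.approx(want, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            v.roc_auc([0.1, 0.9], [1, 1])


class TestConfusion:
    def test_printed_trial_counts(self):
        """22/24 responders and 7/19 non-responders correct at 0.5 gives
        sensitivity 91.7% and specificity 36.8%."""
        probs = np.r_[np.full(22, 0.9), np.full(2, 0.1),   # responders
                      np.full(12, 0.9), np.full(7, 0.1)]   # non-responders
        y = np.r_[np.ones(24), np.zeros(19)].astype(int)
        c = v.confusion_at_threshold(probs, y, 0.5)
        assert (c["tp"], c["fn"], c["tn"], c["fp"]) == (22, 2, 7, 12)
        assert c["sensitivity"] == 91.7
        assert c["specificity"] == 36.8

    def test_zero_threshold_predicts_everyone_positive(self):
        c = v.confusion_at_threshold([0.2, 0.8, 0.0], [1, 0, 1], 0.0)
        assert c["sensitivity"] == 100.0
        assert c["specificity"] == 0.0

    def test_threshold_is_inclusive(self):
        c = v.confusion_at_threshold([0.5], [1], 0.5)
        assert c["tp"] == 1

    def test_probability_range_checked(self):
        with pytest.raises(ValueError):
            v.confusion_at_threshold([1.2], [1])


class TestOddsTiterCorrelation:
    def test_exact_linear_link_gives_r2_one(self):
        rng = np.random.default_rng(0)
        titer = rng.uniform(0.05, 0.9, 30)
        odds = 1.5 * np.log(titer) + 0.3
        probs = 1 / (1 + np.exp(-odds))
        out = v.odds_titer_correlation(probs, titer, titer / 0.1)
        assert out["r2_titer"] == pytest.approx(1.0, abs=1e-9)
        assert out["p_titer"] < 1e-12

    def test_independent_noise_r2_near_zero(self):
        rng = np.random.default_rng(1)
        r2s, ps = [], []
        for _ in range(20):
            probs = rng.uniform(0.05, 0.95, 40)
            titer = rng.uniform(0.05, 0.9, 40)
            out = v.odds_titer_correlation(probs, titer, titer / 0.1)
            r2s.append(out["r2_titer"])
            ps.append(out["p_titer"])
        assert np.mean(r2s) < 0.12
        assert 0.2 < np.mean(ps) < 0.8

    def test_extreme_probabilities_warn_and_clip(self):
        with pytest.warns(UserWarning, match="clipped"):
            out = v.odds_titer_correlation([0.0, 0.5, 1.0],
                                           [0.1, 0.2, 0.3], [1.0, 2.0, 3.0])
        assert np.isfinite(list(out.values())).all()

    def test_planted_monotone_link_detected(self):
        """With titers generated from the cohort model, predicted odds from
        the true causal score correlate with week-12 titer at n=200."""
        cohort = v.generate_cohort(v.SimConfig(n_subjects=200, n_genes=50, seed=31))
        per = cohort.samples.drop_duplicates("subject_id")
        norm = v.normalize(cohort.expression)
        wk2 = cohort.samples[cohort.samples["timepoint"] == "week2"]
        zs = norm.values.loc[cohort.truth.causal_gene_ids, wk2["sample_id"]]
        zs = (zs.T - zs.mean(axis=1)) / zs.std(axis=1)
        score = zs.to_numpy() @ cohort.truth.causal_effects
        probs = 1 / (1 + np.exp(-score / np.linalg.norm(cohort.truth.causal_effects)))
        out = v.odds_titer_correlation(
            probs, per["igg_week12"], per["igg_week12"] / per["igg_week0"]
        )
        assert out["r2_titer"] > 0.1
        assert out["p_titer"] < 1e-3
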