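"""Moderated-t differential expression: OLS stage, shrinkage, BH, contrasts."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import vaxresp as v
from vaxresp.diffexpr import (
    fit_gene_models,
    fit_f_dist,
    moderated_table,
    squeeze_variance,
)


def _two_group_design(n_per=3):
    return pd.DataFrame(
        {"intercept": 1.0, "group": np.r_[np.zeros(n_per), np.ones(n_per)]},
        index=[f"s{j}" for j in range(2 * n_per)],
    )


class TestFitGeneModels:
    def test_hand_numbers_two_groups(self):
        """[1,2,3] vs [3,4,5]: difference 2, pooled variance 1."""
        Y = pd.DataFrame([[1.0, 2, 3, 3, 4, 5]], index=["g1"],
                         columns=[f"s{j}" for j in range(6)])
        fits = fit_gene_models(Y, _two_group_design(), np.array([0.0, 1.0]))
        assert fits.coef[0] == pytest.approx(2.0)
        assert fits.sigma2[0] == pytest.approx(1.0)
        assert fits.df_residual == 4

    def test_identical_groups_zero_coef(self):
        Y = pd.DataFrame([[1.0, 2, 3, 1, 2, 3]], index=["g1"],
                         columns=[f"s{j}" for j in range(6)])
        fits = fit_gene_models(Y, _two_group_design(), np.array([0.0, 1.0]))
        assert fits.coef[0] == pytest.approx(0.0)
        assert fits.sigma2[0] == pytest.approx(1.0)  # within-group spread

    def test_sex_shift_leaves_group_coef_in_balanced_design(self):
        """Adding a constant to one sex stratum moves only the sex coefficient
        when sex and group are orthogonal."""
        design = pd.DataFrame({
            "intercept": 1.0,
            "group": [0, 0, 1, 1, 0, 0, 1, 1],
            "sex": [0, 1, 0, 1, 0, 1, 0, 1],
        }, index=[f"s{j}" for j in range(8)])
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, 8)
        Y = pd.DataFrame([base, base + 5.0 * design["sex"].to_numpy()],
                         index=["g1", "g2"], columns=design.index)
        c = np.array([0.0, 1.0, 0.0])
        fits = fit_gene_models(Y, design, c)
        assert fits.coef[0] == pytest.approx(fits.coef[1])

    def test_rank_deficient_design_raises(self):
        design = _two_group_design()
        design["dup"] = design["group"]
        Y = pd.DataFrame(np.ones((3, 6)), columns=design.index)
        with pytest.raises(ValueError, match="rank"):
            fit_gene_models(Y, design, np.array([0.0, 1.0, 0.0]))


class TestModeration:
    def test_d0_zero_limit_is_ordinary_t(self, two_group_matrix):
        Y, design = two_group_matrix
        fits = fit_gene_models(Y, design, np.array([0.0, 1.0]))
        s2_post = squeeze_variance(fits.sigma2, fits.df_residual, 0.0,
                                   np.ones_like(fits.sigma2))
        table = moderated_table(fits, 0.0, s2_post)
        t_ordinary = fits.coef / (fits.stdev_unscaled * np.sqrt(fits.sigma2))
        merged = table.set_index("gene_id").loc[fits.gene_ids, "t_moderated"]
        np.testing.assert_allclose(merged.to_numpy(), t_ordinary, rtol=1e-12)

    def test_d0_infinite_limit_uses_prior_exactly(self, two_group_matrix):
        Y, design = two_group_matrix
        fits = fit_gene_models(Y, design, np.array([0.0, 1.0]))
        prior = np.full_like(fits.sigma2, 1.7)
        s2_post = squeeze_variance(fits.sigma2, fits.df_residual, np.inf, prior)
        np.testing.assert_array_equal(s2_post, prior)
        table = moderated_table(fits, np.inf, s2_post)
        expected = fits.coef / (fits.stdev_unscaled * np.sqrt(1.7))
        merged = table.set_index("gene_id").loc[fits.gene_ids, "t_moderated"]
        np.testing.assert_allclose(merged.to_numpy(), expected, rtol=1e-12)

    def test_identical_variances_give_infinite_d0(self):
        sigma2 = np.full(50, 2.5)
        d0, s2_prior = fit_f_dist(sigma2, df=4, trend=False)
        assert np.isinf(d0)
        np.testing.assert_allclose(s2_prior, 2.5)

    def test_matches_limma_on_fixture(self, two_group_matrix, tmp_path):
        """Independent oracle: R limma eBayes on the same matrix."""
        Y, design = two_group_matrix
        fits = fit_gene_models(Y, design, np.array([0.0, 1.0]))
        state, table = v.ebayes_moderate(fits, trend=False)
        Y.to_csv(tmp_path / "y.csv")
        script = f"""
        suppressMessages(library(limma))
        y <- as.matrix(read.csv("{tmp_path}/y.csv", row.names=1))
        design <- cbind(1, c(rep(0,6), rep(1,6)))
        fit <- eBayes(lmFit(y, design), trend=FALSE)
        out <- data.frame(gene=rownames(y), t=fit$t[,2], p=fit$p.value[,2],
                          d0=fit$df.prior, s2p=fit$s2.prior)
        write.csv(out, "{tmp_path}/limma.csv", row.names=FALSE)
        """
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv").set_index("gene")
        mine = table.set_index("gene_id").loc[ref.index]
        assert state.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-8)
        assert state.s2_prior[0] == pytest.approx(ref["s2p"].iloc[0], rel=1e-8)
        np.testing.assert_allclose(mine["t_moderated"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(mine["p"], ref["p"], rtol=1e-8)

    def test_moderated_t_less_dispersed_than_ordinary(self, two_group_matrix):
        Y, design = two_group_matrix
        fits = fit_gene_models(Y, design, np.array([0.0, 1.0]))
        _, table = v.ebayes_moderate(fits, trend=False)
        t_mod = table["t_moderated"].to_numpy()
        t_ord = fits.coef / (fits.stdev_unscaled * np.sqrt(fits.sigma2))
        assert np.var(t_mod) <= np.var(t_ord)

    def test_requires_ten_genes(self):
        Y = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 6)),
                         columns=_two_group_design().index)
        fits = fit_gene_models(Y, _two_group_design(), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="10"):
            v.ebayes_moderate(fits)


class TestBHAdjust:
    def test_hand_oracle(self):
        np.testing.assert_allclose(
            v.bh_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_and_tied_values_unchanged(self):
        assert v.bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(v.bh_adjust(np.full(5, 0.07)), 0.07)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                v.bh_adjust(np.array(bad))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2,
                    max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_permutation_equivariance(self, ps):
        p = np.array(ps)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(p))
        direct = v.bh_adjust(p)
        unperm = np.empty_like(direct)
        unperm[perm] = v.bh_adjust(p[perm])
        np.testing.assert_allclose(direct, unperm, rtol=1e-12)

    def test_adjusted_at_least_raw(self, two_group_matrix):
        Y, design = two_group_matrix
        fits = fit_gene_models(Y, design, np.array([0.0, 1.0]))
        _, table = v.ebayes_moderate(fits, trend=False)
        assert (table["p_adj"] >= table["p"] - 1e-15).all()


class TestDeContrast:
    def test_equal_timepoints_give_zero_delta_coefs(self, small_cohort, labels):
        expr = v.normalize(small_cohort.expression)
        wk0_of = {}
        for _, row in small_cohort.samples.iterrows():
            if row["timepoint"] == "week0":
                wk0_of[row["subject_id"]] = row["sample_id"]
        frozen = expr.values.copy()
        for _, row in small_cohort.samples.iterrows():
            if row["timepoint"] == "week2":
                frozen[row["sample_id"]] = frozen[wk0_of[row["subject_id"]]]
        expr2 = v.ExpressionMatrix(frozen, "log_normalized")
        out = v.de_contrast(expr2, small_cohort.samples, labels, "delta_RvsNR")
        np.testing.assert_allclose(out.results["log2fc"], 0.0, atol=1e-12)
        assert out.n_significant == 0

    def test_direction_matches_sign_of_mean_difference(self, small_cohort,
                                                       normalized, labels):
        out = v.de_contrast(normalized, small_cohort.samples, labels,
                            "week2_RvsNR")
        assert (out.results["direction"]
                == np.where(out.results["log2fc"] >= 0, "up", "down")).all()
        assert out.results["p"].is_monotonic_increasing

    def test_planted_genes_land_in_top50(self):
        """Six genes shifted by 1.5 SD between 24 responders and 19
        non-responders land in the top 50 by p-value, across seeds."""
        n_r, n_nr, n_genes = 24, 19, 300
        rows = []
        for i in range(n_r + n_nr):
            for tp in ("week0", "week2"):
                rows.append({"sample_id": f"p{i}_{tp}", "subject_id": f"p{i}",
                             "timepoint": tp,
                             "sex": ["F", "M"][i % 2],
                             "batch": ["trial1", "trial2"][(i // 2) % 2],
                             "igg_week0": 0.1,
                             "igg_week12": 0.3 if i < n_r else 0.1,
                             "od450_1to80": 0.2})
        samples = pd.DataFrame(rows)
        labels = v.classify_response(samples)
        planted = [f"g{i}" for i in range(6)]
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            values = pd.DataFrame(
                rng.normal(0, 1, (n_genes, len(samples))),
                index=[f"g{i}" for i in range(n_genes)],
                columns=samples["sample_id"],
            )
            r_wk2 = [f"p{i}_week2" for i in range(n_r)]
            values.loc[planted, r_wk2] += 1.5
            expr = v.ExpressionMatrix(values, "log_normalized")
            out = v.de_contrast(expr, samples, labels, "week2_RvsNR")
            assert set(planted) <= set(out.top["gene_id"])

    def test_too_few_samples_per_group_raises(self):
        rows = []
        for i, resp in enumerate([1, 0, 0, 0]):
            for tp in ("week0", "week2"):
                rows.append({"sample_id": f"p{i}_{tp}", "subject_id": f"p{i}",
                             "timepoint": tp, "sex": "F", "batch": "trial1",
                             "igg_week0": 0.1,
                             "igg_week12": 0.3 if resp else 0.1,
                             "od450_1to80": 0.2})
        samples = pd.DataFrame(rows)
        labels = v.classify_response(samples)
        values = pd.DataFrame(
            np.random.default_rng(0).normal(size=(12, 8)),
            index=[f"g{i}" for i in range(12)],
            columns=samples["sample_id"],
        )
        expr = v.ExpressionMatrix(values, "log_normalized")
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="2 samples per group"):
                v.de_contrast(expr, samples, labels, "baseline_RvsNR")
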