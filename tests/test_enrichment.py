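"""GSVA-style enrichment: walk oracle, symmetries, pathway contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import vaxresp as v
from vaxresp.data import ExpressionMatrix, GeneSetCollection
from vaxresp.enrichment import kernel_cdf_statistic


def _expr(values: np.ndarray) -> ExpressionMatrix:
    g, n = values.shape
    return ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(g)],
                     columns=[f"s{j}" for j in range(n)]),
        "log_normalized",
    )


def brute_force_gsva(values: np.ndarray, member: np.ndarray, tau: float = 1.0):
    """Literal re-enactment of the kernel-CDF + weighted-KS walk, written
    with explicit loops and no shared code with the implementation."""
    p, n = values.shape
    z = np.zeros((p, n))
    for g in range(p):
        sd = np.std(values[g], ddof=1)
        if sd == 0:
            continue
        h = sd / 4.0
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += stats.norm.cdf((values[g, j] - values[g, k]) / h)
            z[g, j] = acc / n
    scores = np.zeros(n)
    center = (p + 1) / 2.0
    for j in range(n):
        order = sorted(range(p), key=lambda g: (-z[g, j], g))
        weights = {}
        for pos, g in enumerate(order, start=1):
            weights[g] = abs(center - pos) ** tau
        wsum = sum(weights[g] for g in order if member[g])
        n_miss = p - int(member.sum())
        nu, hit, miss = [], 0.0, 0.0
        for g in order:
            if member[g]:
                hit += weights[g] / wsum
            else:
                miss += 1.0 / n_miss
            nu.append(hit - miss)
        scores[j] = max(max(nu), 0.0) + min(min(nu), 0.0)
    return scores


class TestGsvaScores:
    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        values = rng.normal(5, 2, (10, 4))
        # push a 3-gene set to the top of sample 0's ranking
        values[:3, 0] += 6.0
        member = np.zeros(10, dtype=bool)
        member[:3] = True
        expr = _expr(values)
        sets = GeneSetCollection({"top3": ["g0", "g1", "g2"]})
        got = v.gsva_scores(expr, sets, min_size=3).loc["top3"].to_numpy()
        want = brute_force_gsva(values, member)
        np.testing.assert_allclose(got, want, rtol=1e-10)
        assert got[0] == got.max()

    def test_mirrored_rankings_give_opposite_scores(self):
        """Reversing a sample's gene ranking flips the sign of every set
        score: the rank weights are symmetric about the middle rank, so
        the random walk runs backwards."""
        from vaxresp.enrichment import _walk_score

        rng = np.random.default_rng(5)
        p = 12
        order = rng.permutation(p)
        mirrored = order[::-1].copy()
        ranks = np.empty(p)
        ranks[order] = np.arange(1, p + 1)
        weights = np.abs((p + 1) / 2.0 - ranks)  # identical in both samples
        member = np.zeros(p, dtype=bool)
        member[[0, 3, 7, 9, 11]] = True
        fwd = _walk_score(order, weights, member)
        rev = _walk_score(mirrored, weights, member)
        assert fwd == pytest.approx(-rev, abs=1e-12)

    def test_complete_set_scores_zero(self):
        rng = np.random.default_rng(7)
        expr = _expr(rng.normal(0, 1, (8, 5)))
        sets = GeneSetCollection({"all": [f"g{i}" for i in range(8)]})
        scores = v.gsva_scores(expr, sets)
        np.testing.assert_array_equal(scores.loc["all"], 0.0)

    def test_affine_per_gene_transform_invariance(self):
        """Scaling/shifting a gene scales its bandwidth too, leaving the
        kernel-CDF statistic and therefore all scores unchanged."""
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, (15, 6))
        expr = _expr(values)
        transformed = values * rng.uniform(0.5, 3.0, (15, 1)) + rng.normal(
            0, 5, (15, 1)
        )
        expr2 = _expr(transformed)
        sets = GeneSetCollection({"s": ["g1", "g4", "g6", "g10", "g13"]})
        pd.testing.assert_frame_equal(
            v.gsva_scores(expr, sets), v.gsva_scores(expr2, sets)
        )

    def test_small_sets_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.normal(0, 1, (10, 4)))
        sets = GeneSetCollection({"tiny": ["g0", "g1"],
                                  "ok": [f"g{i}" for i in range(5)]})
        with pytest.warns(UserWarning, match="tiny"):
            scores = v.gsva_scores(expr, sets)
        assert list(scores.index) == ["ok"]

    def test_constant_gene_statistic_zero(self):
        values = np.vstack([np.full(4, 3.0),
                            np.random.default_rng(0).normal(0, 1, (4, 4))])
        z = kernel_cdf_statistic(values)
        np.testing.assert_array_equal(z[0], 0.0)

    def test_needs_two_samples(self):
        expr = _expr(np.random.default_rng(0).normal(0, 1, (10, 1)))
        sets = GeneSetCollection({"s": [f"g{i}" for i in range(5)]})
        with pytest.raises(ValueError, match="2 samples"):
            v.gsva_scores(expr, sets)


class TestDifferentialPathways:
    @staticmethod
    def _samples_and_labels(n_r, n_nr):
        rows = []
        for i in range(n_r + n_nr):
            rows.append({"sample_id": f"p{i}_week0", "subject_id": f"p{i}",
                         "timepoint": "week0",
                         "sex": ["F", "M"][i % 2],
                         "batch": ["trial1", "trial2"][(i // 2) % 2],
                         "igg_week0": 0.1,
                         "igg_week12": 0.3 if i < n_r else 0.1,
                         "od450_1to80": 0.45})
        samples = pd.DataFrame(rows)
        return samples, v.classify_response(samples)

    def test_equal_group_profiles_no_significant_sets(self):
        """Responders and non-responders with identical score profiles
        yield zero group effects and no significant pathways."""
        samples, labels = self._samples_and_labels(6, 6)
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, (12, 6))
        cols = {s: base[:, i % 6] for i, s in enumerate(samples["sample_id"])}
        scores = pd.DataFrame(cols, index=[f"set{i}" for i in range(12)])
        out = v.differential_pathways(scores, samples, labels, "baseline_RvsNR")
        np.testing.assert_allclose(out.results["log2fc"], 0.0, atol=1e-12)
        assert out.n_significant == 0

    def test_planted_set_separates_groups(self):
        """A pathway score shifted by 1.5 SD between 13 responders and 33
        non-responders reaches p <= 0.05 in most seeds."""
        samples, labels = self._samples_and_labels(13, 33)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            scores = pd.DataFrame(
                rng.normal(0, 1, (12, 46)),
                index=[f"set{i}" for i in range(12)],
                columns=samples["sample_id"],
            )
            scores.loc["set0", samples["sample_id"][:13]] += 1.5
            out = v.differential_pathways(scores, samples, labels,
                                          "baseline_RvsNR")
            row = out.results.set_index("gene_id").loc["set0"]
            hits += row["p"] <= 0.05
        assert hits >= 9

    def test_permuted_labels_give_uniform_pvalues(self):
        samples, labels = self._samples_and_labels(10, 10)
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(20):
            scores = pd.DataFrame(
                rng.normal(0, 1, (15, 20)),
                index=[f"set{i}" for i in range(15)],
                columns=samples["sample_id"],
            )
            out = v.differential_pathways(scores, samples, labels,
                                          "baseline_RvsNR")
            ps.extend(out.results["p"].tolist())
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_hr_contrast_supported(self, small_cohort, normalized, labels):
        sets = GeneSetCollection({
            f"set{i}": list(np.random.default_rng(i).choice(
                normalized.gene_ids, 8, replace=False))
            for i in range(12)
        })
        scores = v.gsva_scores(normalized, sets)
        out = v.differential_pathways(scores, small_cohort.samples, labels,
                                      "HRvsNR")
        assert len(out.results) == 12
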