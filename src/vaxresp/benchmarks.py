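"""Recovery and calibration benchmarks on synthetic study conditions.

The study's own numbers (its AUROC, correlation R-squared values, DEG
counts, gene identities) depend on the real cohort; what can be
checked without it is that every algorithm recovers planted structure
under the emulated design.  Each function here runs one benchmark
from scratch and returns plain numbers; the test suite asserts on
them and the reproduction script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, GeneSetCollection
from .diffexpr import ebayes_moderate, fit_gene_models
from .enrichment import gsva_scores
from .fci import direct_neighbors, fci_max_orient
from .mgm import MgmParams, MixedDataset, MixedGraphicalModel
from .prediction import confusion_at_threshold, lasso_logistic_cv, roc_auc
from .preprocess import classify_response, normalize
from .simulate import OUTCOME_NODE, SimConfig, generate_cohort, random_sparse_mgm
from .stability import stars_select


def printed_confusion() -> dict:
    """Confusion arithmetic on the trial's printed counts.

    22 of 24 true responders predicted positive and 7 of 19 true
    non-responders predicted negative at the 0.5 threshold.
    """
    probs = np.r_[np.full(22, 0.9), np.full(2, 0.1),
                  np.full(12, 0.9), np.full(7, 0.1)]
    labels = np.r_[np.ones(24), np.zeros(19)].astype(int)
    return confusion_at_threshold(probs, labels, threshold=0.5)


def auroc_oracle_gap(n_instances: int = 100, seed: int = 0) -> float:
    """Max |rank AUROC - exhaustive pairwise concordance| over random
    instances with n <= 50 (ties forced)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_instances:
        n = int(rng.integers(4, 51))
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        p = rng.choice(np.linspace(0, 1, 11), n)
        pos, neg = p[y == 1], p[y == 0]
        conc = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
        want = conc / (len(pos) * len(neg))
        worst = max(worst, abs(roc_auc(p, y).auroc - want))
        done += 1
    return worst


def _cohort_week2_labels(cohort):
    norm = normalize(cohort.expression)
    labels = classify_response(cohort.samples)
    wk2 = cohort.samples[cohort.samples["timepoint"] == "week2"]
    y = wk2["subject_id"].map(labels.response).map({"NR": 0, "R": 1})
    y.index = wk2["sample_id"].to_numpy()
    return norm, wk2, y


def predictor_recovery(n_seeds: int = 20, n_subjects: int = 200,
                       n_genes: int = 500, seed: int = 0) -> dict:
    """Nested-CV LASSO on cohorts with six 1.5-SD planted causal genes."""
    aurocs, hits4 = [], 0
    for s in range(n_seeds):
        cohort = generate_cohort(
            SimConfig(n_subjects=n_subjects, n_genes=n_genes, seed=seed + s)
        )
        norm, _, y = _cohort_week2_labels(cohort)
        model = lasso_logistic_cv(norm.subset_samples(y.index), y, seed=seed + s)
        aurocs.append(roc_auc(model.heldout_probabilities, model.labels).auroc)
        n_causal = len(set(model.selected_features)
                       & set(cohort.truth.causal_gene_ids))
        hits4 += n_causal >= 4
    return {
        "mean_heldout_auroc": float(np.mean(aurocs)),
        "frac_seeds_4of6_selected": hits4 / n_seeds,
    }


def null_de_fraction(n_genes: int = 2000, n_per_group: int = 10,
                     seed: int = 0) -> float:
    """Fraction of p <= 0.05 for pure-noise genes under the moderated t."""
    rng = np.random.default_rng(seed)
    Y = pd.DataFrame(
        rng.normal(0.0, 1.0, (n_genes, 2 * n_per_group)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(2 * n_per_group)],
    )
    design = pd.DataFrame(
        {"intercept": 1.0,
         "group": np.r_[np.zeros(n_per_group), np.ones(n_per_group)]},
        index=Y.columns,
    )
    fits = fit_gene_models(Y, design, np.array([0.0, 1.0]))
    _, table = ebayes_moderate(fits)
    return float((table["p"] <= 0.05).mean())


def null_heldout_auroc(n_seeds: int = 20, n_subjects: int = 60,
                       n_genes: int = 80, seed: int = 0) -> float:
    """Mean held-out AUROC on cohorts with zero planted effects."""
    aurocs = []
    for s in range(n_seeds):
        cohort = generate_cohort(SimConfig(
            n_subjects=n_subjects, n_genes=n_genes,
            causal_effects=np.zeros(6), seed=seed + s,
        ))
        norm, _, y = _cohort_week2_labels(cohort)
        model = lasso_logistic_cv(norm.subset_samples(y.index), y,
                                  seed=seed + s)
        aurocs.append(roc_auc(model.heldout_probabilities, model.labels).auroc)
    return float(np.mean(aurocs))


def mgm_skeleton_f1(n_seeds: int = 20, n_samples: int = 1000,
                    seed: int = 0) -> float:
    """Mean skeleton F1 on random sparse mixed graphs (7 cont + 3 binary),
    penalty chosen per dataset by the instability sweep."""
    f1s = []
    for s in range(n_seeds):
        frame, kinds, truth = random_sparse_mgm(n_samples=n_samples,
                                                seed=seed + s)
        data = MixedDataset(frame, kinds)
        lam = stars_select(data, seed=seed + s)
        est = MixedGraphicalModel(lam, lam, lam, max_iter=800, tol=1e-7)
        est.fit(data)
        found = est.graph_.skeleton_pairs()
        tp = len(found & truth)
        denom = 2 * tp + len(found - truth) + len(truth - found)
        f1s.append(2 * tp / denom if denom else 1.0)
    return float(np.mean(f1s))


def mgm_grid_oracle_gap(n_samples: int = 500, seed: int = 0) -> float:
    """Objective gap between the proximal-gradient optimum and an
    exhaustive grid search on a 3-variable Gaussian instance."""
    from .mgm import _Problem

    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n_samples)
    y = x + rng.normal(0, 1, n_samples)
    z = y + rng.normal(0, 1, n_samples)
    df = pd.DataFrame({"X": x, "Y": y, "Z": z})
    data = MixedDataset(df, {})
    problem = _Problem(data)
    params = MgmParams(0.25, 0.25, 0.25)

    def objective(b12, b13, b23):
        th = problem.init_theta()
        th.beta[0, 1] = th.beta[1, 0] = b12
        th.beta[0, 2] = th.beta[2, 0] = b13
        th.beta[1, 2] = th.beta[2, 1] = b23
        return problem.smooth_loss(th) + problem.penalty(th, params)

    best = np.inf
    for b12 in np.linspace(0.0, 0.8, 81):
        for b13 in np.linspace(0.0, 0.4, 41):
            for b23 in np.linspace(0.0, 0.8, 81):
                best = min(best, objective(b12, b13, b23))
    est = MixedGraphicalModel(0.25, 0.25, 0.25, tol=1e-10, max_iter=5000)
    est.fit(df)
    th = est.theta_
    mine = objective(th.beta[0, 1], th.beta[0, 2], th.beta[1, 2])
    return float(mine - best)  # negative or ~0: optimizer at least as good


def collider_orientation_rate(n_seeds: int = 20, n_samples: int = 2000,
                              seed: int = 0) -> float:
    """Fraction of seeds in which X -> Z <- Y is oriented with both
    arrowheads into Z."""
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + s)
        x = rng.normal(0, 1, n_samples)
        y = rng.normal(0, 1, n_samples)
        z = x - y + rng.normal(0, 1, n_samples)
        df = pd.DataFrame({"X": x, "Y": y, "Z": z})
        est = MixedGraphicalModel(0.25, 0.25, 0.25)
        est.fit(df)
        pag = fci_max_orient(est.graph_, df)
        hits += (
            pag.has_edge("X", "Z") and pag.has_edge("Y", "Z")
            and not pag.has_edge("X", "Y")
            and pag.edge("X", "Z").mark_at("Z") == "arrow"
            and pag.edge("Y", "Z").mark_at("Z") == "arrow"
        )
    return hits / n_seeds


def direct_neighbor_recovery(n_seeds: int = 20, n_subjects: int = 500,
                             seed: int = 0) -> dict:
    """Recall of the six planted causal genes among the PAG's direct
    neighbors of the week-12 IgG node, plus edge-sign agreement."""
    recalls, sign_ok, sign_tot = [], 0, 0
    for s in range(n_seeds):
        cohort = generate_cohort(
            SimConfig(n_subjects=n_subjects, n_genes=60, seed=seed + s)
        )
        norm = normalize(cohort.expression)
        wk2 = cohort.samples[cohort.samples["timepoint"] == "week2"]
        ids = wk2["sample_id"].tolist()
        meta = wk2.set_index("sample_id").loc[ids]
        truth = cohort.truth
        genes = (truth.causal_gene_ids
                 + [truth.neighbor_map[c][0] for c in truth.causal_gene_ids]
                 + ["G00001", "G00002"])
        frame = norm.values.loc[genes, ids].T.copy()
        frame[OUTCOME_NODE] = np.log(meta["igg_week12"].to_numpy(dtype=float))
        frame["sex"] = meta["sex"].to_numpy()
        frame["batch"] = meta["batch"].to_numpy()
        data = MixedDataset(frame.reset_index(drop=True), {})
        est = MixedGraphicalModel(0.25, 0.25, 0.25, tol=1e-7)
        est.fit(data)
        pag = fci_max_orient(est.graph_, data, max_cond_size=2)
        found = {d["node"]: d["sign"]
                 for d in direct_neighbors(pag, OUTCOME_NODE)}
        truth_signs = dict(zip(truth.causal_gene_ids, truth.causal_signs))
        recalls.append(sum(g in found for g in truth_signs))
        for g, sign in found.items():
            if g in truth_signs:
                sign_tot += 1
                sign_ok += sign == truth_signs[g]
    return {
        "mean_recall_of_6": float(np.mean(recalls)),
        "sign_agreement": sign_ok / sign_tot if sign_tot else float("nan"),
    }


def gsva_checks(seed: int = 0) -> dict:
    """Antisymmetry, complete-set-zero and brute-force walk agreement."""
    from .enrichment import _walk_score

    rng = np.random.default_rng(seed)
    p = 12
    order = rng.permutation(p)
    ranks = np.empty(p)
    ranks[order] = np.arange(1, p + 1)
    weights = np.abs((p + 1) / 2.0 - ranks)
    member = np.zeros(p, dtype=bool)
    member[[0, 3, 7, 9, 11]] = True
    antisym = abs(_walk_score(order, weights, member)
                  + _walk_score(order[::-1].copy(), weights, member))

    values = rng.normal(0, 1, (8, 5))
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(8)],
                     columns=[f"s{j}" for j in range(5)]),
        "log_normalized",
    )
    complete = float(np.abs(gsva_scores(
        expr, GeneSetCollection({"all": [f"g{i}" for i in range(8)]})
    ).to_numpy()).max())

    # brute-force re-enactment of the kernel CDF + walk on 10 genes
    vals = rng.normal(5, 2, (10, 4))
    vals[:3, 0] += 6.0
    z = np.zeros((10, 4))
    for g in range(10):
        h = np.std(vals[g], ddof=1) / 4.0
        for j in range(4):
            z[g, j] = np.mean([stats.norm.cdf((vals[g, j] - vk) / h)
                               for vk in vals[g]])
    scores = np.zeros(4)
    center = (10 + 1) / 2.0
    member10 = np.zeros(10, dtype=bool)
    member10[:3] = True
    for j in range(4):
        order_j = sorted(range(10), key=lambda g: (-z[g, j], g))
        w = {g: abs(center - pos) ** 1.0
             for pos, g in enumerate(order_j, start=1)}
        wsum = sum(w[g] for g in order_j if member10[g])
        nu, hit, miss = [], 0.0, 0.0
        for g in order_j:
            if member10[g]:
                hit += w[g] / wsum
            else:
                miss += 1.0 / 7.0
            nu.append(hit - miss)
        scores[j] = max(max(nu), 0.0) + min(min(nu), 0.0)
    expr10 = ExpressionMatrix(
        pd.DataFrame(vals, index=[f"g{i}" for i in range(10)],
                     columns=[f"s{j}" for j in range(4)]),
        "log_normalized",
    )
    got = gsva_scores(
        expr10, GeneSetCollection({"top3": ["g0", "g1", "g2"]}), min_size=3
    ).loc["top3"].to_numpy()
    walk_gap = float(np.abs(got - scores).max())
    return {
        "antisymmetry_gap": float(antisym),
        "complete_set_max_abs": complete,
        "walk_oracle_gap": walk_gap,
    }
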