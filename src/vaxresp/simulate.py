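"""Synthetic vaccine-trial cohorts with planted causal structure.

The generator emulates the design of a two-trial peptide-vaccine study:
each subject contributes paired PBMC transcriptomes at week 0 (baseline)
and week 2 (post first dose), with biological sex and trial batch as
nuisance covariates, an anti-vaccine IgG titer at baseline and week 12,
and a responder label defined by a fold-change threshold on the titer.

A small set of *causal* genes drives the week-12 titer: each subject's
standardized week-2 expression of those genes forms a causal score that
feeds, through a saturating logistic link, the log fold-change of the
titer.  Every causal gene gets a block of correlated but non-causal
neighbor genes, and disjoint nuisance genes are shifted by sex and
batch.  The ground truth (gene identities, effect signs, the planted
graph) is returned alongside the data so structure-recovery can be
scored exactly.

Expression is generated as log-normal latent intensities and emitted as
rounded counts; normalization is left to the preprocessing stage, as
with real RNA-seq data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, RAW_COUNTS, validate_sample_table
from .graphs import ARROW, CIRCLE, MixedGraph, TAIL

OUTCOME_NODE = "IgG_week12"


def _default_effects() -> np.ndarray:
    # six planted genes, three positive and three negative, 1.5-SD scale
    return np.array([1.5, 1.5, 1.5, -1.5, -1.5, -1.5])


@dataclass
class SimConfig:
    """Free parameters of the cohort generator.

    Defaults mirror the emulated study: 69 subjects with responder
    prevalence 24/69, six causal transcripts with signed effects, a
    two-level trial batch, and a 2-fold titer threshold defining
    response.
    """

    n_subjects: int = 69
    n_genes: int = 500
    n_causal: int = 6
    causal_effects: np.ndarray = field(default_factory=_default_effects)
    n_correlated_per_causal: int = 3
    correlation_rho: float = 0.6
    responder_fraction: float = 24 / 69
    batch_labels: tuple[str, str] = ("trial1", "trial2")
    sex_effect_size: float = 0.5
    batch_effect_size: float = 0.5
    n_sex_genes: int = 10
    n_batch_genes: int = 10
    noise_sd: float = 1.0
    intra_subject_corr: float = 0.5
    titer_fold_threshold: float = 2.0
    titer_effect_scale: float = 3.0
    titer_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.causal_effects = np.asarray(self.causal_effects, dtype=float)
        if self.n_causal > self.n_genes:
            raise ValueError(
                f"n_causal ({self.n_causal}) exceeds n_genes ({self.n_genes})"
            )
        if self.causal_effects.shape != (self.n_causal,):
            raise ValueError(
                f"causal_effects must have length n_causal={self.n_causal}"
            )
        if not 0.0 < self.responder_fraction < 1.0:
            raise ValueError("responder_fraction must lie strictly in (0, 1)")
        if not -1.0 < self.correlation_rho < 1.0:
            raise ValueError("correlation_rho must lie in (-1, 1)")
        if self.noise_sd <= 0 or self.titer_noise_sd <= 0:
            raise ValueError("noise SDs must be positive")
        if not 0.0 <= self.intra_subject_corr < 1.0:
            raise ValueError("intra_subject_corr must lie in [0, 1)")
        n_special = (
            self.n_causal * (1 + self.n_correlated_per_causal)
            + self.n_sex_genes
            + self.n_batch_genes
        )
        if n_special > self.n_genes:
            raise ValueError(
                f"need at least {n_special} genes for causal/neighbor/nuisance "
                f"structure, got n_genes={self.n_genes}"
            )


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    causal_gene_ids: list[str]
    causal_effects: np.ndarray
    neighbor_map: dict[str, list[str]]
    sex_gene_ids: list[str]
    batch_gene_ids: list[str]
    outcome_node: str = OUTCOME_NODE

    @property
    def causal_signs(self) -> np.ndarray:
        return np.sign(self.causal_effects).astype(int)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    samples: pd.DataFrame
    truth: GroundTruth
    config: SimConfig


def _gene_names(config: SimConfig) -> tuple[list[str], dict[str, list[str]], list[str], list[str]]:
    causal = [f"CAUS{i + 1:03d}" for i in range(config.n_causal)]
    neighbors = {
        c: [f"NB{i + 1:03d}_{j + 1}" for j in range(config.n_correlated_per_causal)]
        for i, c in enumerate(causal)
    }
    sex_genes = [f"SEXG{i + 1:03d}" for i in range(config.n_sex_genes)]
    batch_genes = [f"BATG{i + 1:03d}" for i in range(config.n_batch_genes)]
    n_special = (
        len(causal)
        + sum(len(v) for v in neighbors.values())
        + len(sex_genes)
        + len(batch_genes)
    )
    background = [f"G{i + 1:05d}" for i in range(config.n_genes - n_special)]
    all_genes = (
        causal
        + [g for c in causal for g in neighbors[c]]
        + sex_genes
        + batch_genes
        + background
    )
    return all_genes, neighbors, sex_genes, batch_genes


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Draw one cohort; identical config + seed gives identical output."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, icc = config.n_subjects, config.intra_subject_corr
    sd_subj = config.noise_sd * np.sqrt(icc)
    sd_tp = config.noise_sd * np.sqrt(1.0 - icc)

    all_genes, neighbor_map, sex_genes, batch_genes = _gene_names(config)
    causal = list(neighbor_map)
    g_index = {g: i for i, g in enumerate(all_genes)}
    p = len(all_genes)

    mu = rng.uniform(3.0, 10.0, size=p)  # log2 baseline abundance per gene

    # latent log2 expression: subject random effect shared across timepoints
    subj_eff = rng.normal(0.0, sd_subj, size=(n, p))
    z = {
        tp: mu[None, :] + subj_eff + rng.normal(0.0, sd_tp, size=(n, p))
        for tp in ("week0", "week2")
    }

    # correlated neighbors: mix the causal gene's centered latent with
    # fresh noise so each neighbor has pairwise correlation ~ rho
    rho = config.correlation_rho
    for c in causal:
        ci = g_index[c]
        for nb in neighbor_map[c]:
            ni = g_index[nb]
            for tp in ("week0", "week2"):
                fresh = rng.normal(0.0, config.noise_sd, size=n)
                z[tp][:, ni] = mu[ni] + rho * (z[tp][:, ci] - mu[ci]) + np.sqrt(
                    1.0 - rho**2
                ) * fresh

    # covariates
    sex = rng.choice(["F", "M"], size=n)
    batch = rng.choice(list(config.batch_labels), size=n)
    for tp in ("week0", "week2"):
        for g in sex_genes:
            z[tp][:, g_index[g]] += config.sex_effect_size * (sex == "F")
        for g in batch_genes:
            z[tp][:, g_index[g]] += config.batch_effect_size * (
                batch == config.batch_labels[1]
            )

    # causal score from standardized week-2 expression of the causal genes
    if config.n_causal > 0:
        causal_idx = [g_index[c] for c in causal]
        zc = (z["week2"][:, causal_idx] - mu[causal_idx]) / config.noise_sd
        score = zc @ config.causal_effects
        score_sd = float(np.linalg.norm(config.causal_effects))
        liability = score / score_sd if score_sd > 0 else np.zeros(n)
    else:
        liability = np.zeros(n)

    # titer: multiplicative fold-change with a saturating logistic link.
    # Location calibrated so that with zero causal signal the responder
    # fraction equals config.responder_fraction.
    log2_thresh = np.log2(config.titer_fold_threshold)
    signal = config.titer_effect_scale * (2.0 * stats.logistic.cdf(liability) - 1.0)
    loc = log2_thresh - config.titer_noise_sd * stats.norm.ppf(
        1.0 - config.responder_fraction
    )
    log2_fold = loc + signal + rng.normal(0.0, config.titer_noise_sd, size=n)
    igg_week0 = np.exp(rng.normal(np.log(0.08), 0.4, size=n))
    igg_week12 = igg_week0 * 2.0**log2_fold
    od450 = igg_week12  # OD-scale titer readout at the 1:80 dilution

    # emit rounded counts on the natural scale, with a per-sample size factor
    subjects = [f"SUBJ{i + 1:03d}" for i in range(n)]
    rows = []
    columns = {}
    for tp in ("week0", "week2"):
        size_factors = np.exp(rng.normal(0.0, 0.1, size=n))
        counts = np.rint(2.0 ** z[tp] * size_factors[:, None]).astype(np.int64)
        for i, subj in enumerate(subjects):
            sample_id = f"{subj}_{tp}"
            columns[sample_id] = counts[i]
            rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": subj,
                    "timepoint": tp,
                    "sex": sex[i],
                    "batch": batch[i],
                    "igg_week0": igg_week0[i],
                    "igg_week12": igg_week12[i],
                    "od450_1to80": od450[i],
                }
            )

    values = pd.DataFrame(columns, index=all_genes)
    expression = ExpressionMatrix(values, RAW_COUNTS)
    samples = validate_sample_table(pd.DataFrame(rows))
    truth = GroundTruth(
        causal_gene_ids=causal,
        causal_effects=config.causal_effects.copy(),
        neighbor_map=neighbor_map,
        sex_gene_ids=sex_genes,
        batch_gene_ids=batch_genes,
    )
    return SyntheticCohort(expression, samples, truth, config)


def random_sparse_mgm(
    n_continuous: int = 7,
    n_categorical: int = 3,
    n_levels: int = 2,
    edge_prob: float = 0.2,
    n_samples: int = 1000,
    beta_cc: float = 0.35,
    rho_cd: float = 0.8,
    phi_dd: float = 1.0,
    n_sweeps: int = 300,
    seed: int = 0,
):
    """Draw data from a random sparse pairwise mixed graphical model.

    Edges are included independently with ``edge_prob``; parameters are
    signed constants (continuous-continuous ``beta_cc``, level-contrast
    ``rho_cd`` and ``phi_dd``).  Sampling runs ``n_samples`` independent
    Gibbs chains in parallel for ``n_sweeps`` sweeps, so draws are
    i.i.d. across rows.  Returns ``(frame, kinds, true_pairs)`` where
    ``true_pairs`` is the set of frozenset node pairs with an edge.

    The continuous block's implied precision matrix is kept diagonally
    dominant by rescaling if needed, so the joint model is proper.
    """
    rng = np.random.default_rng(seed)
    cont = [f"C{i + 1}" for i in range(n_continuous)]
    disc = [f"D{j + 1}" for j in range(n_categorical)]
    names = cont + disc
    p, q = n_continuous, n_categorical

    beta = np.zeros((p, p))
    true_pairs: set[frozenset] = set()
    for s in range(p):
        for t in range(s + 1, p):
            if rng.random() < edge_prob:
                beta[s, t] = beta[t, s] = rng.choice([-1.0, 1.0]) * beta_cc
                true_pairs.add(frozenset((cont[s], cont[t])))
    # keep I - beta diagonally dominant (proper Gaussian sector)
    row = np.abs(beta).sum(axis=1).max()
    if row >= 0.9:
        beta *= 0.9 / row
    # centered level contrasts for discrete couplings
    base = np.linspace(-1.0, 1.0, n_levels)
    base -= base.mean()
    rho = np.zeros((p, q, n_levels))
    for s in range(p):
        for j in range(q):
            if rng.random() < edge_prob:
                rho[s, j] = rng.choice([-1.0, 1.0]) * rho_cd * base / 2.0
                true_pairs.add(frozenset((cont[s], disc[j])))
    phi = np.zeros((q, q, n_levels, n_levels))
    for j in range(q):
        for k in range(j + 1, q):
            if rng.random() < edge_prob:
                m = phi_dd * np.outer(base, base)
                phi[j, k] = rng.choice([-1.0, 1.0]) * m
                phi[k, j] = phi[j, k].T
                true_pairs.add(frozenset((disc[j], disc[k])))

    X = rng.normal(0.0, 1.0, size=(n_samples, p))
    D = rng.integers(0, n_levels, size=(n_samples, q))
    levels_onehot = np.eye(n_levels)
    for _ in range(n_sweeps):
        for s in range(p):
            mean = X @ beta[s] + sum(rho[s, j][D[:, j]] for j in range(q))
            X[:, s] = mean + rng.normal(0.0, 1.0, size=n_samples)
        for j in range(q):
            logits = np.zeros((n_samples, n_levels))
            for s in range(p):
                logits += np.outer(X[:, s], rho[s, j])
            for k in range(q):
                if k != j:
                    logits += levels_onehot[D[:, k]] @ phi[k, j]
            logits -= logits.max(axis=1, keepdims=True)
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            D[:, j] = (probs.cumsum(axis=1) < rng.random((n_samples, 1))).sum(axis=1)

    frame = pd.DataFrame(X, columns=cont)
    for j, name in enumerate(disc):
        frame[name] = pd.Series(D[:, j]).map(lambda l: f"l{l}")
    kinds = {c: "continuous" for c in cont} | {d: "categorical" for d in disc}
    return frame, kinds, true_pairs


def truth_graph(cohort: SyntheticCohort) -> MixedGraph:
    """Planted graph: causal genes -> outcome, neighbors tied to their gene."""
    truth = cohort.truth
    g = MixedGraph()
    g.add_node(truth.outcome_node)
    for gene, effect in zip(truth.causal_gene_ids, truth.causal_effects):
        g.add_edge(gene, truth.outcome_node, mark_a=TAIL, mark_b=ARROW,
                   sign=int(np.sign(effect)))
        for nb in truth.neighbor_map[gene]:
            rho_sign = int(np.sign(cohort.config.correlation_rho))
            g.add_edge(gene, nb, mark_a=CIRCLE, mark_b=CIRCLE, sign=rho_sign)
    g.add_node("sex")
    g.add_node("batch")
    return g
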