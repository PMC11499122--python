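"""Single-sample gene-set enrichment (GSVA-style random walk).

For every gene a cross-sample Gaussian-kernel CDF statistic is
computed; genes are re-ranked within each sample by that statistic and
a weighted Kolmogorov-Smirnov random walk over the ranking scores each
gene set in each sample.  The default score is the signed sum of the
maximum positive and maximum negative deviations of the walk
(``mx_diff``); a two-sided-maximum variant is exposed as a flag.

Scores are cohort-relative: the kernel CDF is estimated across the
samples handed in, so adding or removing samples re-anchors the
statistic.  Differential-pathway testing reuses the moderated-t
machinery with pathways in the role of genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .data import ExpressionMatrix, GeneSetCollection, LOG_NORMALIZED
from .diffexpr import DEOutcome, de_on_matrix


def kernel_cdf_statistic(values: np.ndarray) -> np.ndarray:
    """Cross-sample Gaussian-kernel CDF per gene.

    ``values`` is genes x samples; bandwidth is the per-gene sample
    SD / 4.  A constant gene gets statistic 0 in every sample.
    """
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    out = np.zeros_like(values)
    sd = values.std(axis=1, ddof=1) if n > 1 else np.zeros(p)
    for g in range(p):
        if sd[g] <= 0:
            continue
        h = sd[g] / 4.0
        diff = (values[g][:, None] - values[g][None, :]) / h
        out[g] = stats.norm.cdf(diff).mean(axis=1)
    return out


def _walk_score(order: np.ndarray, weights: np.ndarray, member: np.ndarray,
                mx_diff: bool = True) -> float:
    """Weighted KS random walk down one sample's gene ranking.

    ``order`` lists gene indices from best to worst rank; ``weights``
    are the walk weights per gene; ``member`` flags set membership.
    """
    w = weights[order]
    m = member[order]
    p = len(order)
    n_miss = p - int(m.sum())
    if n_miss == 0:
        return 0.0
    hit_total = w[m].sum()
    hit = np.cumsum(np.where(m, w, 0.0)) / (hit_total if hit_total > 0 else 1.0)
    miss = np.cumsum(np.where(m, 0.0, 1.0)) / n_miss
    nu = hit - miss
    if mx_diff:
        return float(max(nu.max(), 0.0) + min(nu.min(), 0.0))
    i = int(np.argmax(np.abs(nu)))
    return float(nu[i])


class GSVA(BaseEstimator, TransformerMixin):
    """Per-sample gene-set enrichment transformer.

    Parameters
    ----------
    tau : float
        Exponent on the rank weight |center - rank|^tau.
    min_size : int
        Sets with fewer matched genes are dropped with a warning.
    mx_diff : bool
        Signed max-deviation-sum score (default) versus the two-sided
        maximum-deviation variant.
    """

    def __init__(self, tau: float = 1.0, min_size: int = 5, mx_diff: bool = True):
        self.tau = tau
        self.min_size = min_size
        self.mx_diff = mx_diff

    def fit(self, X: pd.DataFrame, y=None, gene_sets: GeneSetCollection | None = None):
        """X is samples x genes; gene sets are matched to its columns."""
        if gene_sets is None:
            raise ValueError("GSVA.fit requires gene_sets")
        X = pd.DataFrame(X)
        if X.shape[0] < 2:
            raise ValueError("GSVA needs >= 2 samples for the kernel CDF")
        genes = list(X.columns)
        restricted = gene_sets.restrict(genes, min_size=self.min_size)
        dropped = set(gene_sets.sets) - set(restricted.sets)
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} gene set(s) with < {self.min_size} "
                f"matched genes: {sorted(dropped)}"
            )
        if len(restricted) == 0:
            raise ValueError("no gene set survived the size filter")
        self.gene_ids_ = genes
        self.gene_sets_ = restricted
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Return samples x sets enrichment scores for X (samples x genes)."""
        X = pd.DataFrame(X)
        if list(X.columns) != self.gene_ids_:
            X = X.loc[:, self.gene_ids_]
        values = X.to_numpy(dtype=float).T        # genes x samples
        z = kernel_cdf_statistic(values)
        p, n = z.shape
        center = (p + 1) / 2.0
        gene_index = {g: i for i, g in enumerate(self.gene_ids_)}
        members = {
            name: np.isin(np.arange(p), [gene_index[g] for g in genes])
            for name, genes in self.gene_sets_.sets.items()
        }
        scores = np.zeros((n, len(members)))
        for j in range(n):
            # stable decreasing sort; ties broken by gene position
            order = np.argsort(-z[:, j], kind="mergesort")
            ranks = np.empty(p)
            ranks[order] = np.arange(1, p + 1)
            weights = np.abs(center - ranks) ** self.tau
            for k, (name, member) in enumerate(members.items()):
                scores[j, k] = _walk_score(order, weights, member, self.mx_diff)
        return pd.DataFrame(scores, index=X.index, columns=list(members))

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).transform(X)


def gsva_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    tau: float = 1.0,
    min_size: int = 5,
    mx_diff: bool = True,
) -> pd.DataFrame:
    """Enrichment matrix (sets x samples) from log-normalized expression."""
    if expr.scale != LOG_NORMALIZED:
        raise ValueError("gsva_scores expects log-normalized expression")
    est = GSVA(tau=tau, min_size=min_size, mx_diff=mx_diff)
    sample_by_set = est.fit_transform(expr.values.T, gene_sets=sets)
    out = sample_by_set.T
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite enrichment scores")
    return out


def differential_pathways(
    scores: pd.DataFrame,
    samples: pd.DataFrame,
    labels,
    contrast: str,
    trend: bool = False,
    p_threshold: float = 0.05,
    top_n: int = 50,
) -> DEOutcome:
    """Moderated-t contrast on the sets x samples score matrix."""
    return de_on_matrix(
        scores, samples, labels, contrast,
        trend=trend, p_threshold=p_threshold, top_n=top_n,
    )
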