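"""Trend-moderated differential expression (limma-trend style).

Each gene is fit by ordinary least squares against a shared design
matrix; residual variances are then shrunk toward a prior that is
either constant or a lowess trend in average expression, by fitting a
scaled F distribution to the sample variances via the method of
moments on the log scale.  The moderated t statistic uses the
posterior variance and gains the prior degrees of freedom.

The empirical-Bayes machinery follows the classic moderated-t
derivation: with residual variances s_g^2 on df_g degrees of freedom
and a prior s_0^2 on d_0 degrees of freedom,

    s_post^2 = (d_0 s_0^2 + df s_g^2) / (d_0 + df)
    t_g = beta_g / (u_g * s_post),   t_g ~ t(d_0 + df)

where u_g is the unscaled standard deviation of the contrast
coefficient.  d_0 = 0 recovers the ordinary t test; d_0 = +inf pools
all genes to the prior variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix, LOG_NORMALIZED
from .preprocess import DesignInfo, build_design, delta_matrix


@dataclass
class GeneFits:
    """Per-gene OLS summaries for one contrast."""

    gene_ids: list[str]
    coef: np.ndarray            # contrast-weighted coefficient (log2 FC)
    stdev_unscaled: np.ndarray  # sqrt(c' (X'X)^-1 c), shared across genes
    sigma2: np.ndarray          # residual variance per gene
    df_residual: float
    avg_expr: np.ndarray


@dataclass
class EBayesState:
    d0: float
    s2_prior: np.ndarray  # per-gene prior variance (constant if no trend)
    s2_post: np.ndarray


def fit_gene_models(
    Y: pd.DataFrame,
    design: pd.DataFrame,
    contrast: np.ndarray,
) -> GeneFits:
    """OLS per gene: Y rows are genes, columns match design rows."""
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank-deficient")
    df_residual = n - k
    if df_residual < 1:
        raise ValueError(f"no residual degrees of freedom (n={n}, k={k})")
    Ym = Y.to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    B = Ym @ X @ XtX_inv.T                      # genes x k coefficients
    resid = Ym - B @ X.T
    sigma2 = (resid**2).sum(axis=1) / df_residual
    c = np.asarray(contrast, dtype=float)
    coef = B @ c
    stdev_unscaled = float(np.sqrt(c @ XtX_inv @ c))
    return GeneFits(
        gene_ids=list(Y.index),
        coef=coef,
        stdev_unscaled=np.full(len(Y), stdev_unscaled),
        sigma2=sigma2,
        df_residual=float(df_residual),
        avg_expr=Ym.mean(axis=1),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton, monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def fit_f_dist(
    sigma2: np.ndarray,
    df: float,
    avg_expr: np.ndarray | None = None,
    trend: bool = True,
    lowess_frac: float = 0.5,
) -> tuple[float, np.ndarray]:
    """Method-of-moments fit of a scaled F distribution to sample variances.

    Returns (d0, s2_prior); s2_prior is per-gene when ``trend`` is on
    (a lowess of log variance against average expression), otherwise a
    constant vector.  If the excess spread of log variances is zero or
    negative, d0 = +inf (complete pooling).
    """
    s2 = np.maximum(np.asarray(sigma2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    if trend and avg_expr is not None and len(np.unique(avg_expr)) > 2:
        fitted = lowess(e, avg_expr, frac=lowess_frac, return_sorted=False)
        e_mean = np.asarray(fitted, dtype=float)
    else:
        e_mean = np.full_like(e, e.mean())
    n = len(e)
    ev = ((e - e_mean) ** 2).sum() / max(n - 1, 1) if n > 1 else 0.0
    excess = ev - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        # with no excess spread the prior is the plain average variance
        # (fitted trend values when a trend is in force)
        if trend and avg_expr is not None and len(np.unique(avg_expr)) > 2:
            s2_prior = np.exp(e_mean)
        else:
            s2_prior = np.full_like(e_mean, s2.mean())
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s2_prior = np.exp(
            e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
        )
    return float(d0), s2_prior


def squeeze_variance(
    sigma2: np.ndarray, df: float, d0: float, s2_prior: np.ndarray
) -> np.ndarray:
    """Posterior variance: convex combination of prior and residual."""
    sigma2 = np.asarray(sigma2, dtype=float)
    s2_prior = np.broadcast_to(np.asarray(s2_prior, dtype=float), sigma2.shape)
    if np.isinf(d0):
        return s2_prior.copy()
    return (d0 * s2_prior + df * sigma2) / (d0 + df)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ebayes_moderate(
    fits: GeneFits, trend: bool = True, lowess_frac: float = 0.5
) -> tuple[EBayesState, pd.DataFrame]:
    """Moderate per-gene variances and return the DE table sorted by p."""
    if len(fits.gene_ids) < 10:
        raise ValueError("need >= 10 genes for stable hyperparameter estimation")
    d0, s2_prior = fit_f_dist(
        fits.sigma2, fits.df_residual, fits.avg_expr, trend=trend,
        lowess_frac=lowess_frac,
    )
    s2_post = squeeze_variance(fits.sigma2, fits.df_residual, d0, s2_prior)
    state = EBayesState(d0=d0, s2_prior=s2_prior, s2_post=s2_post)
    table = moderated_table(fits, d0, s2_post)
    return state, table


def moderated_table(fits: GeneFits, d0: float, s2_post: np.ndarray) -> pd.DataFrame:
    t = fits.coef / (fits.stdev_unscaled * np.sqrt(s2_post))
    df_total = fits.df_residual + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    table = pd.DataFrame(
        {
            "gene_id": fits.gene_ids,
            "log2fc": fits.coef,
            "avg_expr": fits.avg_expr,
            "t_moderated": t,
            "p": p,
            "p_adj": bh_adjust(p),
            "direction": np.where(fits.coef >= 0, "up", "down"),
        }
    )
    return table.sort_values(["p", "gene_id"], kind="mergesort").reset_index(drop=True)


@dataclass
class DEOutcome:
    """Full DE table plus the headline counts for one contrast."""

    results: pd.DataFrame
    n_up: int
    n_down: int
    top: pd.DataFrame
    design_info: DesignInfo
    ebayes: EBayesState
    p_threshold: float = 0.05

    @property
    def n_significant(self) -> int:
        return self.n_up + self.n_down


def de_on_matrix(
    values: pd.DataFrame,
    samples: pd.DataFrame,
    labels,
    contrast: str,
    trend: bool = True,
    p_threshold: float = 0.05,
    top_n: int = 50,
) -> DEOutcome:
    """DE machinery on any features x samples matrix (genes or pathways)."""
    info = build_design(samples, labels, contrast)
    if info.mode == "delta":
        Y = delta_matrix(values, info)
    else:
        Y = values.loc[:, info.column_ids]
    counts = info.group.value_counts()
    if counts.min() < 2:
        raise ValueError("need >= 2 samples per group")
    fits = fit_gene_models(Y, info.design, info.contrast)
    state, table = ebayes_moderate(fits, trend=trend)
    sig = table[table["p"] <= p_threshold]
    return DEOutcome(
        results=table,
        n_up=int((sig["direction"] == "up").sum()),
        n_down=int((sig["direction"] == "down").sum()),
        top=table.head(top_n),
        design_info=info,
        ebayes=state,
        p_threshold=p_threshold,
    )


def de_contrast(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    labels,
    contrast: str,
    trend: bool = True,
    p_threshold: float = 0.05,
    top_n: int = 50,
) -> DEOutcome:
    """Design -> per-gene OLS -> moderation for one responder contrast.

    Significance is called at raw p <= ``p_threshold``; BH-adjusted
    p-values are reported alongside but not used for the calls.
    """
    if expr.scale != LOG_NORMALIZED:
        raise ValueError("de_contrast expects log-normalized expression")
    return de_on_matrix(
        expr.values, samples, labels, contrast,
        trend=trend, p_threshold=p_threshold, top_n=top_n,
    )
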