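"""Pairwise mixed graphical models by penalized pseudolikelihood.

The model couples continuous (Gaussian-conditional) and categorical
(multinomial-logistic-conditional) variables through pairwise
parameters: a scalar beta_st per continuous pair, a level-vector
rho_sj per continuous-discrete pair, and a level-matrix phi_jk per
discrete pair.  The negative log pseudolikelihood (the sum of all
conditional negative log likelihoods, averaged over samples) is
minimized under group-sparse penalties

    lambda_cc * sum |beta_st| + lambda_cd * sum ||rho_sj||_2
    + lambda_dd * sum ||phi_jk||_F

by proximal gradient descent with backtracking line search.  An edge
is present exactly when its parameter group survives the proximal
shrinkage.  Continuous variables are z-scored internally and their
conditional variances fixed at one, which makes the smooth part of
the objective jointly convex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .graphs import CIRCLE, MixedGraph

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass
class MgmParams:
    """Penalty triple and optimizer controls."""

    lambda_cc: float = 0.25
    lambda_cd: float = 0.25
    lambda_dd: float = 0.25
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.lambda_cc, self.lambda_cd, self.lambda_dd) <= 0:
            raise ValueError("penalties must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class MixedDataset:
    """Complete-case samples over continuous and categorical variables."""

    frame: pd.DataFrame
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.kinds) - set(self.frame.columns)
        if unknown:
            raise ValueError(f"kinds refer to absent variables: {sorted(unknown)}")
        for col in self.frame.columns:
            if col not in self.kinds:
                is_num = pd.api.types.is_numeric_dtype(self.frame[col])
                self.kinds[col] = CONTINUOUS if is_num else CATEGORICAL
        if self.frame.isna().any().any():
            raise ValueError("missing values are not allowed (complete cases only)")
        for col, kind in self.kinds.items():
            if kind == CATEGORICAL:
                levels = sorted(self.frame[col].astype(str).unique())
                if len(levels) < 2:
                    raise ValueError(f"categorical {col!r} has a single level")

    @property
    def continuous(self) -> list[str]:
        return [c for c in self.frame.columns if self.kinds[c] == CONTINUOUS]

    @property
    def categorical(self) -> list[str]:
        return [c for c in self.frame.columns if self.kinds[c] == CATEGORICAL]

    def levels(self, col: str) -> list[str]:
        return sorted(self.frame[col].astype(str).unique())


@dataclass
class _Theta:
    """Parameter block container supporting vector-space arithmetic."""

    alpha: np.ndarray                       # (p,)
    beta: np.ndarray                        # (p, p) symmetric, zero diag
    rho: list                               # [s][j] -> (L_j,)
    psi: list                               # [j] -> (L_j,)
    phi: dict = field(default_factory=dict)  # (j, k), j<k -> (L_j, L_k)

    def copy(self) -> "_Theta":
        return _Theta(
            self.alpha.copy(), self.beta.copy(),
            [[v.copy() for v in row] for row in self.rho],
            [v.copy() for v in self.psi],
            {k: v.copy() for k, v in self.phi.items()},
        )

    def axpy(self, a: float, other: "_Theta") -> "_Theta":
        """self + a * other, returned as a new _Theta."""
        return _Theta(
            self.alpha + a * other.alpha,
            self.beta + a * other.beta,
            [[u + a * v for u, v in zip(r1, r2)] for r1, r2 in zip(self.rho, other.rho)],
            [u + a * v for u, v in zip(self.psi, other.psi)],
            {k: self.phi[k] + a * other.phi[k] for k in self.phi},
        )

    def diff_sq_norm(self, other: "_Theta") -> float:
        tot = float(((self.alpha - other.alpha) ** 2).sum())
        tot += float(((self.beta - other.beta) ** 2).sum()) / 2.0  # shared pairs
        for r1, r2 in zip(self.rho, other.rho):
            for u, v in zip(r1, r2):
                tot += float(((u - v) ** 2).sum())
        for u, v in zip(self.psi, other.psi):
            tot += float(((u - v) ** 2).sum())
        for k in self.phi:
            tot += float(((self.phi[k] - other.phi[k]) ** 2).sum())
        return tot

    def inner_diff(self, grad: "_Theta", other: "_Theta") -> float:
        """<grad, self - other> respecting the shared beta parametrization."""
        tot = float((grad.alpha * (self.alpha - other.alpha)).sum())
        tot += float((grad.beta * (self.beta - other.beta)).sum()) / 2.0
        for gr, r1, r2 in zip(grad.rho, self.rho, other.rho):
            for g, u, v in zip(gr, r1, r2):
                tot += float((g * (u - v)).sum())
        for g, u, v in zip(grad.psi, self.psi, other.psi):
            tot += float((g * (u - v)).sum())
        for k in grad.phi:
            tot += float((grad.phi[k] * (self.phi[k] - other.phi[k])).sum())
        return tot


class _Problem:
    """Preprocessed arrays and the objective/gradient of one dataset."""

    def __init__(self, data: MixedDataset):
        self.cont = data.continuous
        self.disc = data.categorical
        X = data.frame[self.cont].to_numpy(dtype=float) if self.cont else np.zeros(
            (len(data.frame), 0)
        )
        self.x_mean = X.mean(axis=0) if X.size else np.zeros(0)
        sd = X.std(axis=0, ddof=0) if X.size else np.zeros(0)
        self.x_sd = np.where(sd > 0, sd, 1.0)
        self.X = (X - self.x_mean) / self.x_sd
        self.n = len(data.frame)
        self.levels = [data.levels(c) for c in self.disc]
        self.D = []
        for col, levels in zip(self.disc, self.levels):
            codes = data.frame[col].astype(str).map({l: i for i, l in enumerate(levels)})
            onehot = np.zeros((self.n, len(levels)))
            onehot[np.arange(self.n), codes.to_numpy()] = 1.0
            self.D.append(onehot)

    def init_theta(self) -> _Theta:
        p, q = len(self.cont), len(self.disc)
        return _Theta(
            alpha=np.zeros(p),
            beta=np.zeros((p, p)),
            rho=[[np.zeros(len(self.levels[j])) for j in range(q)] for _ in range(p)],
            psi=[np.zeros(len(self.levels[j])) for j in range(q)],
            phi={(j, k): np.zeros((len(self.levels[j]), len(self.levels[k])))
                 for j in range(q) for k in range(j + 1, q)},
        )

    def _cont_means(self, th: _Theta) -> np.ndarray:
        mean = th.alpha[None, :] + self.X @ th.beta
        for j, D in enumerate(self.D):
            rho_j = np.stack([th.rho[s][j] for s in range(len(self.cont))], axis=0)
            mean = mean + D @ rho_j.T
        return mean

    def _disc_logits(self, th: _Theta, j: int) -> np.ndarray:
        logits = np.tile(th.psi[j], (self.n, 1))
        for s in range(len(self.cont)):
            logits = logits + np.outer(self.X[:, s], th.rho[s][j])
        for k, D in enumerate(self.D):
            if k == j:
                continue
            phi = th.phi[(j, k)] if j < k else th.phi[(k, j)].T
            logits = logits + D @ phi.T
        return logits

    def smooth_loss(self, th: _Theta) -> float:
        loss = 0.0
        if self.cont:
            R = self._cont_means(th) - self.X
            loss += 0.5 * float((R**2).sum()) / self.n
        for j in range(len(self.disc)):
            logits = self._disc_logits(th, j)
            logits = logits - logits.max(axis=1, keepdims=True)
            logz = np.log(np.exp(logits).sum(axis=1))
            picked = (logits * self.D[j]).sum(axis=1)
            loss += float((logz - picked).sum()) / self.n
        return loss

    def gradient(self, th: _Theta) -> _Theta:
        g = self.init_theta()
        n = self.n
        p, q = len(self.cont), len(self.disc)
        if p:
            R = self._cont_means(th) - self.X  # n x p
            g.alpha = R.mean(axis=0)
            gb = (self.X.T @ R) / n
            g.beta = gb + gb.T
            np.fill_diagonal(g.beta, 0.0)
        P = []
        for j in range(q):
            logits = self._disc_logits(th, j)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            P.append(e / e.sum(axis=1, keepdims=True))
        for j in range(q):
            E = P[j] - self.D[j]
            g.psi[j] = E.mean(axis=0)
            for s in range(p):
                g.rho[s][j] = (self.D[j].T @ R[:, s]) / n + (E.T @ self.X[:, s]) / n
            for k in range(j + 1, q):
                Ek = P[k] - self.D[k]
                g.phi[(j, k)] = (E.T @ self.D[k]) / n + ((Ek.T @ self.D[j]) / n).T
        return g

    def penalty(self, th: _Theta, params: MgmParams) -> float:
        p, q = len(self.cont), len(self.disc)
        pen = 0.0
        for s in range(p):
            for t in range(s + 1, p):
                pen += params.lambda_cc * abs(th.beta[s, t])
            for j in range(q):
                pen += params.lambda_cd * float(np.linalg.norm(th.rho[s][j]))
        for key in th.phi:
            pen += params.lambda_dd * float(np.linalg.norm(th.phi[key]))
        return pen

    def prox(self, th: _Theta, params: MgmParams, step: float) -> _Theta:
        out = th.copy()
        p, q = len(self.cont), len(self.disc)
        thr = step * params.lambda_cc
        mag = np.maximum(np.abs(out.beta) - thr, 0.0)
        out.beta = np.sign(out.beta) * mag
        np.fill_diagonal(out.beta, 0.0)
        for s in range(p):
            for j in range(q):
                norm = float(np.linalg.norm(out.rho[s][j]))
                shrink = max(1.0 - step * params.lambda_cd / norm, 0.0) if norm > 0 else 0.0
                out.rho[s][j] = out.rho[s][j] * shrink
        for key in out.phi:
            norm = float(np.linalg.norm(out.phi[key]))
            shrink = max(1.0 - step * params.lambda_dd / norm, 0.0) if norm > 0 else 0.0
            out.phi[key] = out.phi[key] * shrink
        return out


def _optimize(problem: _Problem, params: MgmParams) -> tuple[_Theta, list[float], bool]:
    th = problem.init_theta()
    step = 1.0
    path = [problem.smooth_loss(th) + problem.penalty(th, params)]
    converged = False
    for _ in range(params.max_iter):
        f_cur = problem.smooth_loss(th)
        grad = problem.gradient(th)
        while True:
            cand = problem.prox(th.axpy(-step, grad), params, step)
            f_new = problem.smooth_loss(cand)
            quad = (
                f_cur
                + cand.inner_diff(grad, th)
                + cand.diff_sq_norm(th) / (2.0 * step)
            )
            if f_new <= quad + 1e-12 or step < 1e-10:
                break
            step *= 0.5
        obj = f_new + problem.penalty(cand, params)
        path.append(obj)
        rel = abs(path[-2] - obj) / max(abs(path[-2]), 1.0)
        th = cand
        if rel < params.tol:
            converged = True
            break
        step = min(step * 2.0, 1.0)  # gentle step recovery
    return th, path, converged


class MixedGraphicalModel(BaseEstimator):
    """Sparse pairwise MGM structure learner (scikit-learn style).

    ``fit`` accepts a DataFrame (or :class:`MixedDataset`); variable
    kinds are inferred from dtypes unless given.  After fitting,
    ``graph_`` holds the skeleton with circle-circle endpoint marks and
    continuous-continuous edge signs.
    """

    def __init__(self, lambda_cc: float = 0.25, lambda_cd: float = 0.25,
                 lambda_dd: float = 0.25, max_iter: int = 500, tol: float = 1e-6,
                 edge_eps: float = 1e-8):
        self.lambda_cc = lambda_cc
        self.lambda_cd = lambda_cd
        self.lambda_dd = lambda_dd
        self.max_iter = max_iter
        self.tol = tol
        self.edge_eps = edge_eps

    def _params(self) -> MgmParams:
        return MgmParams(self.lambda_cc, self.lambda_cd, self.lambda_dd,
                         self.max_iter, self.tol)

    def fit(self, X, kinds: dict[str, str] | None = None):
        data = X if isinstance(X, MixedDataset) else MixedDataset(pd.DataFrame(X), dict(kinds or {}))
        if len(data.frame) < 5:
            raise ValueError("need at least 5 samples")
        problem = _Problem(data)
        theta, path, converged = _optimize(problem, self._params())
        if not converged:
            grad = problem.gradient(theta)
            gnorm = np.sqrt(grad.diff_sq_norm(problem.init_theta()))
            warnings.warn(
                f"MGM did not converge in {self.max_iter} iterations "
                f"(final gradient norm {gnorm:.3g})"
            )
        self.data_ = data
        self.theta_ = theta
        self.objective_path_ = path
        self.converged_ = converged
        self.graph_ = self._extract_graph(problem, theta)
        return self

    def _extract_graph(self, problem: _Problem, th: _Theta) -> MixedGraph:
        g = MixedGraph()
        for name in problem.cont + problem.disc:
            g.add_node(name)
        p, q = len(problem.cont), len(problem.disc)
        for s in range(p):
            for t in range(s + 1, p):
                if abs(th.beta[s, t]) > self.edge_eps:
                    g.add_edge(problem.cont[s], problem.cont[t],
                               CIRCLE, CIRCLE, sign=int(np.sign(th.beta[s, t])))
            for j in range(q):
                if np.linalg.norm(th.rho[s][j]) > self.edge_eps:
                    g.add_edge(problem.cont[s], problem.disc[j], CIRCLE, CIRCLE, sign=0)
        for (j, k), phi in th.phi.items():
            if np.linalg.norm(phi) > self.edge_eps:
                g.add_edge(problem.disc[j], problem.disc[k], CIRCLE, CIRCLE, sign=0)
        return g


def pseudolikelihood_objective(data: MixedDataset, theta: _Theta,
                               params: MgmParams) -> float:
    """Penalized objective for external optimizer cross-checks."""
    problem = _Problem(data)
    return problem.smooth_loss(theta) + problem.penalty(theta, params)


def learn_mgm(data: MixedDataset | pd.DataFrame, params: MgmParams | None = None,
              kinds: dict[str, str] | None = None) -> MixedGraph:
    """Fit the MGM and return its skeleton."""
    params = params or MgmParams()
    est = MixedGraphicalModel(params.lambda_cc, params.lambda_cd, params.lambda_dd,
                              params.max_iter, params.tol)
    est.fit(data, kinds=kinds)
    return est.graph_
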