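"""FCI-MAX orientation of a mixed-data skeleton.

Starting from an undirected skeleton (e.g. learned by the MGM), the
algorithm prunes edges by conditional-independence testing over
conditioning sets up to a maximum size, then orients unshielded
colliders using the MAX rule: among all separating sets of a
non-adjacent pair, the one with the largest test p-value is treated
as the true separator, and a collider is declared exactly when the
middle node is outside it.  The standard FCI propagation rules
(R1-R3) are then applied to closure, yielding a partial ancestral
graph with circle/tail/arrow endpoint marks.

Conditional independence on mixed data is tested by nested-model
likelihood-ratio regressions: linear for a continuous target,
(multinomial) logistic for a categorical target, with the asymptotic
chi-square null.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .graphs import ARROW, CIRCLE, MixedGraph, TAIL
from .mgm import CATEGORICAL, CONTINUOUS, MixedDataset


def _encode(frame: pd.DataFrame, kinds: dict[str, str], col: str) -> np.ndarray:
    """Design block for one predictor: z-scored column or reduced one-hot."""
    if kinds[col] == CONTINUOUS:
        x = frame[col].to_numpy(dtype=float)
        sd = x.std() or 1.0
        return ((x - x.mean()) / sd)[:, None]
    levels = sorted(frame[col].astype(str).unique())
    dummies = np.stack(
        [(frame[col].astype(str) == l).to_numpy(float) for l in levels[1:]], axis=1
    )
    return dummies


def _linear_lr_test(y: np.ndarray, Z: np.ndarray, B: np.ndarray) -> float:
    """LR test that B adds nothing over Z for a continuous target."""
    n = len(y)
    X0 = np.column_stack([np.ones(n), Z]) if Z.size else np.ones((n, 1))
    X1 = np.column_stack([X0, B])
    rss0 = float(((y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]) ** 2).sum())
    rss1 = float(((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2).sum())
    rss0, rss1 = max(rss0, 1e-300), max(rss1, 1e-300)
    lr = n * np.log(rss0 / rss1)
    df = B.shape[1]
    return float(stats.chi2.sf(max(lr, 0.0), df))


def _logistic_ll(y_codes: np.ndarray, X: np.ndarray, n_classes: int) -> float:
    if X.shape[1] == 0:
        # intercept-only multinomial: closed form
        counts = np.bincount(y_codes, minlength=n_classes)
        probs = counts / counts.sum()
        return float(np.sum(counts[counts > 0] * np.log(probs[counts > 0])))
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000,
                               tol=1e-8)
    model.fit(X, y_codes)
    p = model.predict_proba(X)
    return float(np.log(np.clip(p[np.arange(len(y_codes)), y_codes], 1e-300, None)).sum())


def _logistic_lr_test(y_codes: np.ndarray, n_classes: int, Z: np.ndarray,
                      B: np.ndarray) -> float:
    ll0 = _logistic_ll(y_codes, Z, n_classes)
    ll1 = _logistic_ll(y_codes, np.column_stack([Z, B]) if Z.size else B, n_classes)
    lr = 2.0 * (ll1 - ll0)
    df = B.shape[1] * (n_classes - 1)
    return float(stats.chi2.sf(max(lr, 0.0), df))


def mixed_ci_test(data: MixedDataset, a: str, b: str, cond: tuple[str, ...]) -> float:
    """p-value for a independent of b given cond, by a nested-model LR test.

    A continuous variable is preferred as the regression target; two
    categorical variables use a multinomial logistic target.  A failed
    or degenerate fit is treated as dependence (p = 0) with a warning.
    """
    frame, kinds = data.frame, data.kinds
    try:
        Z = (
            np.column_stack([_encode(frame, kinds, c) for c in cond])
            if cond else np.zeros((len(frame), 0))
        )
        if kinds[a] == CONTINUOUS or kinds[b] == CONTINUOUS:
            target, other = (a, b) if kinds[a] == CONTINUOUS else (b, a)
            y = frame[target].to_numpy(dtype=float)
            B = _encode(frame, kinds, other)
            return _linear_lr_test(y, Z, B)
        levels = sorted(frame[a].astype(str).unique())
        y_codes = frame[a].astype(str).map({l: i for i, l in enumerate(levels)}).to_numpy()
        B = _encode(frame, kinds, b)
        return _logistic_lr_test(y_codes, len(levels), Z, B)
    except Exception as exc:  # degenerate data: conservative fallback
        warnings.warn(f"CI test {a} _||_ {b} | {cond} failed ({exc}); "
                      "treating as dependent")
        return 0.0


class FCIMax(BaseEstimator):
    """Constraint-based orienter: skeleton + data -> partial ancestral graph."""

    def __init__(self, alpha: float = 0.05, max_cond_size: int = 3):
        self.alpha = alpha
        self.max_cond_size = max_cond_size

    def fit(self, data: MixedDataset, skeleton: MixedGraph):
        graph = skeleton.copy()
        for e in graph.edges:  # PAG starts from circle-circle marks
            e.mark_a = CIRCLE
            e.mark_b = CIRCLE
        self.sepsets_: dict[frozenset, tuple] = {}
        self._prune(graph, data)
        self._orient_colliders(graph, data)
        self._apply_rules(graph)
        self.graph_ = graph
        return self

    # -- phase 1: PC-style edge removal ---------------------------------

    def _prune(self, graph: MixedGraph, data: MixedDataset) -> None:
        for size in range(self.max_cond_size + 1):
            removed = True
            while removed:
                removed = False
                for e in list(graph.edges):
                    a, b = e.a, e.b
                    if not graph.has_edge(a, b):
                        continue
                    pool = sorted(set(graph.neighbors(a) + graph.neighbors(b)) - {a, b})
                    if len(pool) < size:
                        continue
                    for S in combinations(pool, size):
                        p = mixed_ci_test(data, a, b, S)
                        if p > self.alpha:
                            graph.remove_edge(a, b)
                            self.sepsets_[frozenset((a, b))] = tuple(S)
                            removed = True
                            break

    # -- phase 2: MAX-rule collider orientation -------------------------

    def _max_sepset(self, data: MixedDataset, graph: MixedGraph,
                    x: str, y: str) -> tuple | None:
        """Separating set of (x, y) with maximal p; deterministic ties."""
        pool = sorted(set(graph.neighbors(x) + graph.neighbors(y)) - {x, y})
        best: tuple | None = None
        best_key = None
        for size in range(min(self.max_cond_size, len(pool)) + 1):
            for S in combinations(pool, size):
                p = mixed_ci_test(data, x, y, S)
                if p <= self.alpha:
                    continue
                key = (-p, len(S), S)  # max p, then smallest, then lexicographic
                if best_key is None or key < best_key:
                    best_key = key
                    best = S
        return best

    def _orient_colliders(self, graph: MixedGraph, data: MixedDataset) -> None:
        for z in sorted(graph.nodes):
            nbrs = graph.neighbors(z)
            for x, y in combinations(sorted(nbrs), 2):
                if graph.has_edge(x, y):
                    continue
                sep = self._max_sepset(data, graph, x, y)
                if sep is None:
                    continue
                self.sepsets_[frozenset((x, y))] = sep
                if z not in sep:
                    graph.edge(x, z).set_mark(z, ARROW)
                    graph.edge(y, z).set_mark(z, ARROW)

    # -- phase 3: FCI propagation rules R1-R3 ---------------------------

    def _apply_rules(self, graph: MixedGraph) -> None:
        changed = True
        while changed:
            changed = False
            for b in sorted(graph.nodes):
                nbrs = graph.neighbors(b)
                for a in nbrs:
                    for c in nbrs:
                        if a >= c or graph.has_edge(a, c):
                            continue
                        # R1: a *-> b o-* c  =>  a *-> b -> c
                        for u, v in ((a, c), (c, a)):
                            eu, ev = graph.edge(u, b), graph.edge(v, b)
                            if eu.mark_at(b) == ARROW and ev.mark_at(b) == CIRCLE:
                                ev.set_mark(b, TAIL)
                                ev.set_mark(v, ARROW)
                                changed = True
                # R2: chain a -> b *-> c (or a *-> b -> c) with a *-o c
                for a in nbrs:
                    e_ab = graph.edge(a, b)
                    for c in graph.neighbors(b):
                        if c == a or not graph.has_edge(a, c):
                            continue
                        e_bc = graph.edge(b, c)
                        e_ac = graph.edge(a, c)
                        chain1 = (e_ab.mark_at(a) == TAIL and e_ab.mark_at(b) == ARROW
                                  and e_bc.mark_at(c) == ARROW)
                        chain2 = (e_ab.mark_at(b) == ARROW and e_bc.mark_at(b) == TAIL
                                  and e_bc.mark_at(c) == ARROW)
                        if (chain1 or chain2) and e_ac.mark_at(c) == CIRCLE:
                            e_ac.set_mark(c, ARROW)
                            changed = True
            # R3: a *-> b <-* c, a *-o d o-* c, a,c nonadjacent, d o-* b
            for d in sorted(graph.nodes):
                for b in graph.neighbors(d):
                    e_db = graph.edge(d, b)
                    if e_db.mark_at(b) != CIRCLE and e_db.mark_at(d) != CIRCLE:
                        continue
                    common = sorted(set(graph.neighbors(d)) & set(graph.neighbors(b)))
                    for a, c in combinations(common, 2):
                        if graph.has_edge(a, c):
                            continue
                        if (graph.edge(a, b).mark_at(b) == ARROW
                                and graph.edge(c, b).mark_at(b) == ARROW
                                and graph.edge(a, d).mark_at(d) == CIRCLE
                                and graph.edge(c, d).mark_at(d) == CIRCLE
                                and e_db.mark_at(b) == CIRCLE):
                            e_db.set_mark(b, ARROW)
                            changed = True


def fci_max_orient(skeleton: MixedGraph, data: MixedDataset | pd.DataFrame,
                   alpha: float = 0.05, max_cond_size: int = 3,
                   kinds: dict[str, str] | None = None) -> MixedGraph:
    """Prune and orient a skeleton into a PAG (see :class:`FCIMax`)."""
    if not isinstance(data, MixedDataset):
        data = MixedDataset(pd.DataFrame(data), dict(kinds or {}))
    est = FCIMax(alpha=alpha, max_cond_size=max_cond_size)
    est.fit(data, skeleton)
    return est.graph_


def direct_neighbors(graph: MixedGraph, target: str) -> list[dict]:
    """Nodes with an edge pointing into ``target``, by stability then name."""
    if target not in graph.nodes:
        raise KeyError(f"target {target!r} not in graph")
    out = []
    for nb in graph.neighbors(target):
        e = graph.edge(nb, target)
        if e.mark_at(target) == ARROW:
            out.append({"node": nb, "sign": e.sign, "stability": e.stability})
    def sort_key(rec):
        s = rec["stability"]
        return (-(s if s == s else -1.0), rec["node"])  # NaN sorts last
    return sorted(out, key=sort_key)


def neighborhood(graph: MixedGraph, target: str, radius: int = 2) -> list[str]:
    """Neighbors and second neighbors of ``target`` (full-model view)."""
    if target not in graph.nodes:
        raise KeyError(f"target {target!r} not in graph")
    seen = {target}
    frontier = [target]
    for _ in range(radius):
        frontier = [n for f in frontier for n in graph.neighbors(f) if n not in seen]
        seen.update(frontier)
    return sorted(seen - {target})
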