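"""Penalized additive spline smoother with shrunken group intercepts.

Stands in for the generalized additive mixed models used to transfer height
and crown-base information between trees: an additive sum of cubic B-spline
terms (one per covariate) plus a per-group intercept offset (per tree, with a
per-species fallback for sparsely observed trees). The offsets are estimated
with a ridge penalty, so a group's offset shrinks toward zero as its
observation count drops — the same qualitative behaviour as a random
intercept, without the full REML machinery. Smoothing strength is chosen by
generalized cross-validation over a small grid.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["AdditiveSplineSmoother"]


def _spline_knots(x: np.ndarray, n_knots: int, degree: int = 3) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        hi = lo + 1.0
    qs = np.linspace(0, 1, n_knots)
    interior = np.unique(np.quantile(x, qs))
    if interior.size < 2:
        interior = np.array([lo, hi])
    interior[0], interior[-1] = lo, hi
    return np.concatenate([np.full(degree, lo), interior, np.full(degree, hi)])


def _basis(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(xc, knots, degree,
                                 extrapolate=False).toarray()


def _second_diff_penalty(p: int) -> np.ndarray:
    if p < 3:
        return np.eye(p)
    D = np.diff(np.eye(p), n=2, axis=0)
    return D.T @ D


class AdditiveSplineSmoother:
    """y ~ intercept + sum_k spline(x_k) + offset[group].

    Parameters
    ----------
    covariates : names of the smooth terms (order fixes the design).
    n_knots : knots per covariate spline (default 10).
    min_group_obs : groups with fewer observations fall back to their
        fallback label (e.g. tree -> species).
    lambda_grid : multipliers tried for the smoothness penalty (GCV).
    lambda_group : ridge strength on the group offsets.
    """

    def __init__(self, covariates, *, n_knots: int = 10, degree: int = 3,
                 min_group_obs: int = 3,
                 lambda_grid=(0.1, 1.0, 10.0, 100.0),
                 lambda_group: float = 1.0):
        self.covariates = list(covariates)
        self.n_knots = n_knots
        self.degree = degree
        self.min_group_obs = min_group_obs
        self.lambda_grid = tuple(lambda_grid)
        self.lambda_group = lambda_group

    # -- internal -----------------------------------------------------------
    def _fit_effective_groups(self, groups, fallback):
        """Map sparsely observed groups to their fallback label (fit time)."""
        from collections import Counter
        groups = list(groups)
        if fallback is None:
            self._own_groups = set(groups)
            return groups
        fallback = list(fallback)
        counts = Counter(groups)
        self._own_groups = {g for g, c in counts.items()
                            if c >= self.min_group_obs}
        return [g if g in self._own_groups else ("fallback", fb)
                for g, fb in zip(groups, fallback)]

    def _predict_effective_groups(self, groups, fallback):
        groups = list(groups)
        if fallback is None:
            return groups
        return [g if g in self._own_groups else ("fallback", fb)
                for g, fb in zip(groups, list(fallback))]

    def _design(self, X: dict, eff_groups) -> np.ndarray:
        n = len(eff_groups)
        blocks = [np.ones((n, 1))]
        for k, name in enumerate(self.covariates):
            B = _basis(np.asarray(X[name], dtype=float), self.knots_[k],
                       self.degree)
            blocks.append(B - self.basis_means_[k])
        G = np.zeros((n, len(self.group_labels_)))
        index = {g: j for j, g in enumerate(self.group_labels_)}
        for i, g in enumerate(eff_groups):
            j = index.get(g)
            if j is not None:
                G[i, j] = 1.0
        blocks.append(G)
        return np.hstack(blocks)

    # -- API ----------------------------------------------------------------
    def fit(self, X: dict, y, groups=None, fallback=None):
        y = np.asarray(y, dtype=float)
        n = y.size
        for name in self.covariates:
            if name not in X:
                raise ValueError(f"missing covariate {name!r}")
            if np.isnan(np.asarray(X[name], dtype=float)).any():
                raise ValueError(f"covariate {name!r} contains NaN")
        if groups is None:
            groups = np.zeros(n, dtype=object)
        eff = self._fit_effective_groups(groups, fallback)
        # spline bases
        self.knots_, self.basis_means_ = [], []
        for name in self.covariates:
            x = np.asarray(X[name], dtype=float)
            kn = _spline_knots(x, self.n_knots, self.degree)
            self.knots_.append(kn)
            self.basis_means_.append(_basis(x, kn, self.degree).mean(axis=0))
        self.group_labels_ = list(dict.fromkeys(eff))
        D = self._design(X, eff)
        # block penalty
        sizes = [1] + [len(kn) - self.degree - 1 for kn in self.knots_]
        P0 = np.zeros((D.shape[1], D.shape[1]))
        pos = 1
        for k in range(len(self.covariates)):
            p = sizes[k + 1]
            P0[pos:pos + p, pos:pos + p] = _second_diff_penalty(p)
            pos += p
        Pg = np.zeros_like(P0)
        Pg[pos:, pos:] = np.eye(len(self.group_labels_))
        DtD = D.T @ D
        Dty = D.T @ y
        ridge = 1e-8 * np.eye(D.shape[1])
        best = None
        for lam in self.lambda_grid:
            A = DtD + lam * P0 + self.lambda_group * Pg + ridge
            beta = np.linalg.solve(A, Dty)
            edf = float(np.trace(np.linalg.solve(A, DtD)))
            rss = float(np.sum((y - D @ beta) ** 2))
            denom = max(n - edf, 1e-6)
            gcv = n * rss / denom ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam, beta, edf)
        self.gcv_, self.lambda_, self.coef_, self.edf_ = best
        self._spline_dim = pos
        return self

    def predict(self, X: dict, groups=None, fallback=None) -> np.ndarray:
        for name in self.covariates:
            if name not in X:
                raise ValueError(f"missing covariate {name!r}")
        n = len(np.asarray(X[self.covariates[0]]))
        if groups is None:
            groups = np.zeros(n, dtype=object)
        eff = self._predict_effective_groups(groups, fallback)
        D = self._design(X, eff)
        return D @ self.coef_

    def group_offset(self, group) -> float:
        """Fitted intercept offset of one group (0 if unseen)."""
        try:
            j = self.group_labels_.index(group)
        except ValueError:
            return 0.0
        return float(self.coef_[self._spline_dim + j])
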