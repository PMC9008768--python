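"""Sparse canonical correlation by soft-thresholded rank-1 approximation.

The sparse CCA estimates coefficient vectors a (length p, SNPs) and b
(length q, phenotypes) maximizing a' K b, where K is the (weighted)
cross-correlation matrix, subject to unit norms, with sparsity induced
by soft-thresholding a at penalty ``lambda_u`` each iteration (an
elastic-net-like limiting form).  The alternating updates are

    a <- soft(K b, lambda_u) / ||.||,   b <- soft(K' a, lambda_v) / ||.||

i.e. a sparse power iteration for the leading singular pair of K; with
both penalties zero it reproduces the exact leading singular vectors.

On top of the point fit, bootstrap resampling within diagnostic group
yields a variable importance probability (VIP) per SNP — the fraction
of bootstrap replicates in which the SNP's coefficient is nonzero at a
penalty calibrated to select a fixed fraction (default 10%) of SNPs.
SNPs with VIP >= 0.5 form the "priority" set, VIP >= 0.9 the "top-hit"
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .adjust import weighted_standardize
from .datatypes import RefinedSets
from .rv import _weights_array, _wcov

__all__ = [
    "soft_threshold",
    "SparseCCA",
    "scca_fit",
    "weighted_cross_correlation",
    "cv_select_penalty",
    "default_penalty_grid",
    "calibrate_penalty_to_fraction",
    "bootstrap_vip",
    "select_refined_sets",
]


def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise sign(v) * max(|v| - lam, 0)."""
    if lam < 0:
        raise ValueError("threshold must be nonnegative")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def weighted_cross_correlation(X, Y, w=None) -> np.ndarray:
    """p x q weighted cross-correlation matrix.

    Equivalent to the weighted cross-covariance of columns standardized
    to weighted mean 0 / variance 1; zero-variance columns get zero rows
    or columns (they carry no association signal).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    wv = _weights_array(w, X.shape[0])
    Xs, _ = weighted_standardize(X, wv, drop_constant=False)
    Ys, _ = weighted_standardize(Y, wv, drop_constant=False)
    return _wcov(Xs, Ys, wv)


class SparseCCA(BaseEstimator):
    """Sparse rank-1 canonical correlation estimator.

    Parameters
    ----------
    lambda_u : soft-threshold penalty on the SNP coefficients a
    lambda_v : penalty on the phenotype coefficients b (default 0: the
        phenotype combination stays dense)
    tol : convergence tolerance on the max absolute coefficient change
    max_iter : iteration cap

    Attributes (after fit)
    ----------------------
    x_weights_ : a, sparse, unit L2 norm (or all-zero if fully thresholded)
    y_weights_ : b, unit L2 norm
    support_ : boolean mask of nonzero entries of a
    n_iter_, converged_, empty_ : diagnostics
    """

    def __init__(
        self,
        lambda_u: float = 0.0,
        lambda_v: float = 0.0,
        tol: float = 1e-6,
        max_iter: int = 1000,
    ):
        self.lambda_u = lambda_u
        self.lambda_v = lambda_v
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, Y=None, sample_weight=None):
        """Fit from data matrices (X, Y) or a precomputed K when Y is None."""
        if Y is None:
            K = np.asarray(X, dtype=float)
        else:
            K = weighted_cross_correlation(X, Y, sample_weight)
        self.fit_correlation(K)
        return self

    def fit_correlation(self, K: np.ndarray) -> "SparseCCA":
        K = np.asarray(K, dtype=float)
        if not np.isfinite(K).all():
            raise ValueError("cross-correlation matrix contains non-finite values")
        p, q = K.shape

        # initialize b at the leading right singular vector
        if min(p, q) == 0 or not K.any():
            self._set_empty(p, q, 0)
            return self
        _, _, vt = np.linalg.svd(K, full_matrices=False)
        b = vt[0]
        a = np.zeros(p)

        converged = False
        for it in range(1, self.max_iter + 1):
            a_new = soft_threshold(K @ b, self.lambda_u)
            na = np.linalg.norm(a_new)
            if na == 0.0:
                self._set_empty(p, q, it)
                return self
            a_new /= na
            b_new = soft_threshold(K.T @ a_new, self.lambda_v)
            nb = np.linalg.norm(b_new)
            if nb == 0.0:
                self._set_empty(p, q, it)
                return self
            b_new /= nb
            delta = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
            a, b = a_new, b_new
            if delta < self.tol:
                converged = True
                break

        # sign convention: largest-magnitude entry of a positive
        k = int(np.argmax(np.abs(a)))
        if a[k] < 0:
            a, b = -a, -b
        self.x_weights_ = a
        self.y_weights_ = b
        self.support_ = a != 0.0
        self.n_iter_ = it
        self.converged_ = converged
        self.empty_ = False
        self.objective_ = float(a @ K @ b)
        # the alternating updates maximize this penalized criterion (each
        # half-step solves its subproblem exactly), so it is the quantity
        # that is monotone across iterations — a'Kb alone is not
        self.penalized_objective_ = float(
            self.objective_
            - self.lambda_u * np.abs(a).sum()
            - self.lambda_v * np.abs(b).sum()
        )
        return self

    def _set_empty(self, p: int, q: int, it: int) -> None:
        self.x_weights_ = np.zeros(p)
        self.y_weights_ = np.zeros(q)
        self.support_ = np.zeros(p, dtype=bool)
        self.n_iter_ = it
        self.converged_ = True
        self.empty_ = True
        self.objective_ = 0.0
        self.penalized_objective_ = 0.0

    def transform(self, X, Y):
        """Canonical variates (X a, Y b)."""
        return np.asarray(X) @ self.x_weights_, np.asarray(Y) @ self.y_weights_


def scca_fit(
    K: np.ndarray,
    lambda_u: float,
    lambda_v: float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SparseCCA:
    """Functional wrapper: fit :class:`SparseCCA` on a precomputed K."""
    return SparseCCA(
        lambda_u=lambda_u, lambda_v=lambda_v, tol=tol, max_iter=max_iter
    ).fit_correlation(np.asarray(K, dtype=float))


def default_penalty_grid(step: float = 0.0005, upper: float = 0.1) -> np.ndarray:
    """{0} followed by 1e-4, 1e-4 + step, ... up to ``upper``."""
    vals = [0.0]
    v = 1e-4
    while v <= upper + 1e-12:
        vals.append(round(v, 10))
        v += step
    return np.array(vals)


def _weighted_corr(u: np.ndarray, v: np.ndarray, w: np.ndarray) -> float:
    wn = w / w.sum()
    uc = u - wn @ u
    vc = v - wn @ v
    den = np.sqrt((wn @ uc**2) * (wn @ vc**2))
    if den == 0:
        return 0.0
    return float((wn @ (uc * vc)) / den)


def cv_select_penalty(
    X: np.ndarray,
    Y: np.ndarray,
    w=None,
    grid: np.ndarray | None = None,
    folds: int = 10,
    seed: int | None = None,
    lambda_v: float = 0.0,
) -> tuple[float, pd.DataFrame]:
    """Cross-validated penalty search maximizing out-of-fold correlation.

    For each grid value the model is fitted on the training folds and the
    (weighted) correlation of the test-fold canonical variates is summed
    over folds; the maximizer is returned, ties broken toward the
    smallest penalty (the denser model).  Degenerate folds contribute 0.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    wv = _weights_array(w, X.shape[0])
    if grid is None:
        grid = default_penalty_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("penalty grid is empty")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    fold_of = rng.permutation(np.arange(n) % folds)

    totals = np.zeros(grid.size)
    rows = []
    for gi, lam in enumerate(grid):
        for f in range(folds):
            test = fold_of == f
            train = ~test
            if test.sum() < 3 or train.sum() < 3:
                continue
            model = SparseCCA(lambda_u=lam, lambda_v=lambda_v).fit(
                X[train], Y[train], sample_weight=wv[train]
            )
            if model.empty_:
                continue
            u, v = model.transform(X[test], Y[test])
            if np.std(u) == 0 or np.std(v) == 0:
                continue
            totals[gi] += _weighted_corr(u, v, wv[test])
        rows.append({"lambda_u": lam, "cv_correlation_sum": totals[gi]})

    best = grid[np.flatnonzero(totals == totals.max())[0]]
    return float(best), pd.DataFrame(rows)


def calibrate_penalty_to_fraction(
    K: np.ndarray,
    target_fraction: float = 0.10,
    tol_fraction: float = 0.01,
    max_iter: int = 200,
) -> float:
    """Bisection on lambda_u until the selected fraction of SNPs hits target.

    Support size is nonincreasing in the penalty (verified as the search
    proceeds); if the target is unreachable — support sizes jump over the
    tolerance window — the nearest achievable penalty is returned with a
    warning.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target fraction must lie in (0, 1]")
    K = np.asarray(K, dtype=float)
    p = K.shape[0]
    if target_fraction == 1.0:
        return 0.0
    if target_fraction < 1.0 / p:
        warnings.warn(
            f"target fraction {target_fraction} below resolution 1/p = {1 / p:.3g}"
        )

    def frac(lam: float) -> float:
        return scca_fit(K, lambda_u=lam).support_.mean()

    # |(K b)_k| <= ||K_k|| for unit b, so the max row norm zeroes everything
    lo, hi = 0.0, float(np.sqrt((K**2).sum(axis=1)).max())
    f_lo = frac(lo)
    if f_lo <= target_fraction:
        return 0.0
    best_lam, best_gap = lo, abs(f_lo - target_fraction)
    prev_f = f_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = frac(mid)
        if f_mid > prev_f + 1e-12 and mid > lo:
            warnings.warn("support size not monotone at this penalty; continuing")
        gap = abs(f_mid - target_fraction)
        if gap < best_gap:
            best_lam, best_gap = mid, gap
        if gap <= tol_fraction:
            return mid
        if f_mid > target_fraction:
            lo = mid
            prev_f = f_mid
        else:
            hi = mid
        if hi - lo < 1e-12:
            break
    warnings.warn(
        f"calibration plateau: nearest achievable fraction differs from target "
        f"by {best_gap:.3g}"
    )
    return best_lam


@dataclass
class VIPTable:
    """Bootstrap variable importance probabilities per SNP."""

    table: pd.DataFrame  # columns: snp_id, vip, vep, n_selected
    n_bootstrap: int
    lambda_u: float

    @property
    def vip(self) -> np.ndarray:
        return self.table["vip"].to_numpy()

    @property
    def vep(self) -> np.ndarray:
        return self.table["vep"].to_numpy()


def bootstrap_vip(
    X: np.ndarray,
    Y: np.ndarray,
    w,
    groups,
    lambda_u: float,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    snp_ids=None,
    lambda_v: float = 0.0,
) -> VIPTable:
    """Stratified-bootstrap selection frequencies at a fixed penalty.

    Each replicate resamples subjects with replacement within diagnostic
    group, recomputes the weighted cross-correlation, refits the sparse
    CCA at ``lambda_u`` and records the support; VIP_k is the fraction of
    replicates selecting SNP k.  Replicates where a SNP's resample is
    monomorphic contribute a zero coefficient for that SNP; a fully
    degenerate replicate selects nothing.
    """
    if n_bootstrap < 1:
        raise ValueError("need at least one bootstrap replicate")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    wv = _weights_array(w, X.shape[0])
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    p = X.shape[1]

    strata = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
    counts = np.zeros(p, dtype=int)
    for _ in range(n_bootstrap):
        idx = np.concatenate(
            [s[rng.integers(0, s.size, size=s.size)] for s in strata]
        )
        try:
            K = weighted_cross_correlation(X[idx], Y[idx], wv[idx])
        except Exception:
            continue
        model = scca_fit(K, lambda_u=lambda_u, lambda_v=lambda_v)
        if not model.empty_:
            counts += model.support_

    vip = counts / n_bootstrap
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(p)]
    table = pd.DataFrame(
        {
            "snp_id": np.asarray(snp_ids),
            "vip": vip,
            "vep": 1.0 - vip,
            "n_selected": counts,
        }
    )
    return VIPTable(table=table, n_bootstrap=n_bootstrap, lambda_u=lambda_u)


def select_refined_sets(
    vip: VIPTable, priority_cut: float = 0.5, top_cut: float = 0.9
) -> RefinedSets:
    """Priority (VIP >= priority_cut) and top-hit (VIP >= top_cut) id sets."""
    if not (0.0 < priority_cut <= top_cut <= 1.0):
        raise ValueError("cuts must satisfy 0 < priority_cut <= top_cut <= 1")
    t = vip.table
    priority = list(t.loc[t["vip"] >= priority_cut, "snp_id"])
    top = list(t.loc[t["vip"] >= top_cut, "snp_id"])
    if not priority:
        warnings.warn("priority set is empty at this cut-off")
    return RefinedSets(priority=priority, top_hit=top)
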