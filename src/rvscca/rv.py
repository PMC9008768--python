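"""Weighted RV coefficient, permutation test and SNP score decomposition.

The RV coefficient generalizes the squared Pearson correlation to two
matrices X (n x p) and Y (n x q) observed on the same subjects:

    RV = sum_kl S_XY[k,l]^2 / sqrt( sum_kl S_XX[k,l]^2 * sum_kl S_YY[k,l]^2 )

where S are the (cross-)covariance matrices.  The weighted variant uses
inverse-probability-weighted means and covariances, with the weights
pre-standardized to sum to n so that unit weights reduce exactly to the
unweighted sample covariance with divisor n.

The permutation null is generated by jointly permuting the rows of Y
*and their weights* against the fixed rows of X, recomputing the
weighted RV each time; one coherent weight vector (the permuted one) is
used within each permuted dataset.  The p-value uses the add-one
estimator (1 + #{null >= observed}) / (1 + P), which can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import RVTestResult, SNPScoreVector, WeightVector

__all__ = [
    "weighted_cross_covariance",
    "CrossCovariance",
    "rv_coefficient",
    "rv_permutation_test",
    "snp_scores",
]


def _weights_array(w, n: int) -> np.ndarray:
    if w is None:
        return np.ones(n)
    wv = w.weights if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if wv.size != n:
        raise ValueError("weight length must match rows")
    return wv


@dataclass
class CrossCovariance:
    """Weighted covariance summaries entering the RV coefficient."""

    s_xy: np.ndarray
    s_xx: np.ndarray
    s_yy: np.ndarray
    weighted: bool


def _wcov(A: np.ndarray, B: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    mean_a = (w @ A) / w.sum()
    mean_b = (w @ B) / w.sum()
    Ac = A - mean_a
    Bc = B - mean_b
    return (Ac * w[:, None]).T @ Bc / n


def weighted_cross_covariance(
    X: np.ndarray, Y: np.ndarray, w=None
) -> CrossCovariance:
    """S_XY, S_XX, S_YY with weighted means and divisor n.

    With all weights equal to one this reduces exactly to the unweighted
    covariance (1/n) * sum_i (x_ik - xbar_k)(y_il - ybar_l).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    wv = _weights_array(w, X.shape[0])
    return CrossCovariance(
        s_xy=_wcov(X, Y, wv),
        s_xx=_wcov(X, X, wv),
        s_yy=_wcov(Y, Y, wv),
        weighted=w is not None,
    )


def rv_coefficient(S: CrossCovariance) -> float:
    """RV from precomputed covariance summaries; in [0, 1]."""
    num = float((S.s_xy**2).sum())
    den = np.sqrt(float((S.s_xx**2).sum()) * float((S.s_yy**2).sum()))
    if den <= 0.0:
        raise ValueError("RV undefined: a block has zero total covariance")
    return min(1.0, num / den)


def rv_from_matrices(X, Y, w=None) -> float:
    return rv_coefficient(weighted_cross_covariance(X, Y, w))


def rv_permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    w=None,
    n_permutations: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    design: np.ndarray | None = None,
) -> RVTestResult:
    """Permutation test of no linear association between X and Y.

    Rows of Y travel together with their weights under permutation; X
    and its row order stay fixed.

    When X and Y are confounder-adjusted residuals, pass the adjustment
    ``design`` matrix: each permuted Y is then re-residualized on it
    before the RV is recomputed, and one fixed weight vector (the
    observed one, which defines the metric X was orthogonalized in) is
    used throughout.  Without this, both observed blocks lie in the same
    design-orthogonal subspace while permuted Y does not, which inflates
    the observed statistic relative to the null draws by roughly
    n / (n - k) for a k-column design and mis-calibrates the test when
    k / n is not negligible.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    wv = _weights_array(w, X.shape[0])
    if rng is None:
        rng = np.random.default_rng(seed)

    n = X.shape[0]
    draws = np.empty(n_permutations)
    if design is not None:
        from .adjust import weighted_residualize

        D = np.asarray(design, dtype=float)
        observed = rv_from_matrices(X, weighted_residualize(Y, D, wv), wv)
        for b in range(n_permutations):
            perm = rng.permutation(n)
            draws[b] = rv_from_matrices(
                X, weighted_residualize(Y[perm], D, wv), wv
            )
    else:
        observed = rv_from_matrices(X, Y, wv)
        for b in range(n_permutations):
            perm = rng.permutation(n)
            draws[b] = rv_from_matrices(X, Y[perm], wv[perm])
    p = (1.0 + (draws >= observed).sum()) / (1.0 + n_permutations)
    return RVTestResult(
        rv_observed=observed,
        permutation_draws=draws,
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )


def snp_scores(
    s_xy: np.ndarray, snp_ids=None
) -> SNPScoreVector:
    """Per-SNP contribution to the RV numerator, normalized to mean 1.

    ``s_xy`` is the cross-covariance between the refined SNP set and the
    q phenotypes (rows = SNPs); raw_i = sum_j s_xy[i, j]^2.
    """
    s_xy = np.asarray(s_xy, dtype=float)
    if s_xy.ndim != 2 or s_xy.shape[0] == 0:
        raise ValueError("s_xy must be a nonempty SNPs x phenotypes matrix")
    raw = (s_xy**2).sum(axis=1)
    total = raw.sum()
    if total == 0:
        normalized = np.ones_like(raw)
    else:
        normalized = raw * raw.size / total
    if snp_ids is None:
        snp_ids = np.array([f"snp{i}" for i in range(raw.size)])
    return SNPScoreVector(
        snp_ids=np.asarray(snp_ids), raw=raw, normalized=normalized
    )
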