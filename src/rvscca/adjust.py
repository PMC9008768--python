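"""Confounder adjustment by weighted ordinary least squares.

Genotype counts and predicted ROI rates are each regressed on an
intercept, the ancestry principal coordinates and APOE genotype dummies,
using the inverse probability weights; the residuals form the analysis
matrices X and Y.  Residual columns can then be standardized to weighted
mean 0 / variance 1, the scale on which the sparse CCA's
cross-correlation operates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import AncestryCoordinates, WeightVector

__all__ = [
    "build_design",
    "WeightedResidualizer",
    "weighted_residualize",
    "weighted_standardize",
]

_APOE_CODES = {"e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4"}


def build_design(
    covariates: pd.DataFrame,
    coords: AncestryCoordinates | np.ndarray,
    reference_apoe: str | None = None,
) -> pd.DataFrame:
    """Design matrix: intercept + ancestry coordinates + APOE dummies.

    One dummy column per non-reference APOE genotype category present in
    the sample; the reference defaults to the most frequent category.
    Constant coordinate columns are dropped with a warning (rank repair).
    """
    apoe = covariates["apoe"].astype(str)
    bad = set(apoe.unique()) - _APOE_CODES
    if bad:
        raise ValueError(f"unknown APOE genotype code(s): {sorted(bad)}")

    C = coords.coords if isinstance(coords, AncestryCoordinates) else np.asarray(coords)
    if C.shape[0] != len(covariates):
        raise ValueError("coordinate rows must match covariate rows")

    design = pd.DataFrame({"intercept": np.ones(len(covariates))},
                          index=covariates.index)
    for j in range(C.shape[1]):
        col = C[:, j]
        if np.ptp(col) < 1e-12:
            warnings.warn(f"ancestry coordinate {j} is constant; dropped")
            continue
        design[f"coord{j + 1}"] = col

    if reference_apoe is None:
        reference_apoe = apoe.value_counts().idxmax()
    for cat in sorted(apoe.unique()):
        if cat == reference_apoe:
            continue
        design[f"apoe_{cat}"] = (apoe == cat).astype(float)
    return design


def _check_rank(D: np.ndarray) -> None:
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("design matrix is rank deficient")


def weighted_residualize(
    M: np.ndarray | pd.DataFrame,
    design: pd.DataFrame | np.ndarray,
    w: WeightVector | np.ndarray,
) -> np.ndarray:
    """Column-wise weighted OLS residuals of M on the design.

    For each column m, beta_hat = argmin sum_i w_i (m_i - D_i beta)^2 and
    the residual is m - D beta_hat; the result satisfies the weighted
    orthogonality D' W r = 0.
    """
    M_arr = np.asarray(M, dtype=float)
    single = M_arr.ndim == 1
    if single:
        M_arr = M_arr[:, None]
    D = np.asarray(design, dtype=float)
    wv = w.weights if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if not (M_arr.shape[0] == D.shape[0] == wv.size):
        raise ValueError("rows of M, design and weights must align")
    if (wv <= 0).any():
        raise ValueError("weights must be positive")
    _check_rank(D * np.sqrt(wv)[:, None])

    sw = np.sqrt(wv)
    beta, *_ = np.linalg.lstsq(D * sw[:, None], M_arr * sw[:, None], rcond=None)
    resid = M_arr - D @ beta
    return resid[:, 0] if single else resid


def weighted_standardize(
    M: np.ndarray, w: WeightVector | np.ndarray, drop_constant: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Scale columns to weighted mean 0, weighted variance 1.

    Returns the standardized matrix and a boolean mask of retained
    columns; zero-variance columns are dropped with a warning (or zeroed
    when ``drop_constant`` is False).
    """
    wv = w.weights if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    wn = wv / wv.sum()
    mean = wn @ M
    centered = M - mean
    var = wn @ centered**2
    keep = var > 1e-24
    if drop_constant:
        if not keep.all():
            warnings.warn(f"{(~keep).sum()} zero-variance column(s) dropped")
        return centered[:, keep] / np.sqrt(var[keep]), keep
    out = np.zeros_like(centered)
    out[:, keep] = centered[:, keep] / np.sqrt(var[keep])
    return out, np.ones(M.shape[1], dtype=bool)


class WeightedResidualizer(BaseEstimator, TransformerMixin):
    """Transformer: weighted-OLS residuals, optionally standardized.

    Parameters
    ----------
    standardize : rescale residual columns to weighted mean 0 / var 1
        (the cross-correlation scale used by the sparse CCA).

    Call ``fit``/``transform`` with ``design=`` and ``sample_weight=``
    keyword arguments; the fitted coefficients are kept so new rows with
    the same design columns can be residualized consistently.
    """

    def __init__(self, standardize: bool = False):
        self.standardize = standardize

    def fit(self, X, y=None, *, design, sample_weight):
        X = np.asarray(X, dtype=float)
        D = np.asarray(design, dtype=float)
        wv = (
            sample_weight.weights
            if isinstance(sample_weight, WeightVector)
            else np.asarray(sample_weight, dtype=float)
        )
        sw = np.sqrt(wv)
        _check_rank(D * sw[:, None])
        self.coef_, *_ = np.linalg.lstsq(D * sw[:, None], X * sw[:, None], rcond=None)
        resid = X - D @ self.coef_
        if self.standardize:
            wn = wv / wv.sum()
            self.mean_ = wn @ resid
            var = wn @ (resid - self.mean_) ** 2
            self.keep_ = var > 1e-24
            self.scale_ = np.sqrt(var[self.keep_])
        else:
            self.keep_ = np.ones(X.shape[1], dtype=bool)
        return self

    def transform(self, X, *, design):
        X = np.asarray(X, dtype=float)
        D = np.asarray(design, dtype=float)
        resid = X - D @ self.coef_
        if self.standardize:
            return (resid - self.mean_)[:, self.keep_] / self.scale_
        return resid

    def fit_transform(self, X, y=None, **kwargs):
        design = kwargs["design"]
        self.fit(X, design=design, sample_weight=kwargs["sample_weight"])
        return self.transform(X, design=design)
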