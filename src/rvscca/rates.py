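"""Per-ROI linear mixed models and predicted rates of change.

For each region of interest j the model is

    Y_ijt = b0j + b1j*MCI_i + b2j*AD_i + b3j*t + b4j*MCI_i*t + b5j*AD_i*t
            + gamma1_ij + gamma2_ij*t + eps_ijt

with a random intercept and random slope per subject (unstructured 2x2
covariance) fitted by REML.  A subject's predicted rate of change is the
group fixed slope plus the conditional mode (empirical BLUP) of the
random slope:

    rate_ij = b3j + b4j*MCI_i + b5j*AD_i + gamma2_ij_hat

Singular or non-converging fits fall back to maximum likelihood and then
to a random-intercept-only model, with the fallback flagged.  A fast
per-subject ordinary-least-squares alternative (``method="ols"``) skips
shrinkage entirely: each subject's slope is their own least-squares
slope, centered so group means match the group OLS fixed slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ROIMixedModelFit", "fit_roi_lmm", "predict_rates", "ROIRateModel", "qq_normality_check"]

_FIXED_NAMES = ["intercept", "mci", "ad", "month", "mci_month", "ad_month"]


@dataclass
class ROIMixedModelFit:
    """One ROI's fitted mixed model."""

    roi: str
    fixed_effects: pd.Series           # named b0..b5 (see _FIXED_NAMES)
    fixed_se: pd.Series
    cov_re: np.ndarray                 # 2x2 random-effects covariance (per-month slope)
    sigma2: float                      # residual variance
    random_slopes: pd.Series           # conditional mode of gamma2 per subject
    random_intercepts: pd.Series
    converged: bool
    singular: bool
    fallback: str | None = None        # None | "ml" | "intercept_only" | "ols"

    def group_slope(self, group: str) -> float:
        b = self.fixed_effects
        return float(
            b["month"]
            + (b["mci_month"] if group == "MCI" else 0.0)
            + (b["ad_month"] if group == "AD" else 0.0)
        )


def _design(df: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    g = df["subject_id"].map(groups)
    if g.isna().any():
        missing = df.loc[g.isna(), "subject_id"].unique()
        raise KeyError(f"subjects without group labels: {list(missing)[:5]}")
    out = pd.DataFrame(
        {
            "intercept": 1.0,
            "mci": (g == "MCI").astype(float),
            "ad": (g == "AD").astype(float),
            "month": df["month"].astype(float),
        }
    )
    out["mci_month"] = out["mci"] * out["month"]
    out["ad_month"] = out["ad"] * out["month"]
    return out


def _ols_fit(df: pd.DataFrame, roi: str, groups: pd.Series) -> ROIMixedModelFit:
    """Unshrunk fit: per-subject OLS slopes, group-mean decomposition."""
    exog = _design(df, groups)
    y = df["value"].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(exog.to_numpy(), y, rcond=None)
    fixed = pd.Series(beta, index=_FIXED_NAMES)

    slopes = {}
    intercepts = {}
    for sid, sub in df.groupby("subject_id", sort=False):
        t = sub["month"].to_numpy(dtype=float)
        v = sub["value"].to_numpy(dtype=float)
        A = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(A, v, rcond=None)
        intercepts[sid] = coef[0]
        slopes[sid] = coef[1]
    slope_s = pd.Series(slopes)
    grp = slope_s.index.to_series().map(groups)
    gamma2 = slope_s - grp.map(
        lambda g: fixed["month"]
        + (fixed["mci_month"] if g == "MCI" else 0.0)
        + (fixed["ad_month"] if g == "AD" else 0.0)
    )
    resid = y - exog.to_numpy() @ beta
    return ROIMixedModelFit(
        roi=roi,
        fixed_effects=fixed,
        fixed_se=pd.Series(np.nan, index=_FIXED_NAMES),
        cov_re=np.full((2, 2), np.nan),
        sigma2=float(np.var(resid)),
        random_slopes=gamma2,
        random_intercepts=pd.Series(intercepts) - fixed["intercept"],
        converged=True,
        singular=False,
        fallback="ols",
    )


def fit_roi_lmm(
    data: pd.DataFrame,
    roi: str,
    groups: pd.Series | dict,
    method: str = "lmm",
) -> ROIMixedModelFit:
    """Fit the random-intercept / random-slope model for one ROI.

    Parameters
    ----------
    data : long-format frame with columns subject_id, roi, month, value
    roi : which ROI to fit
    groups : subject_id -> {"CN", "MCI", "AD"}
    method : "lmm" (REML mixed model, the default) or "ols"
    """
    import statsmodels.api as sm

    groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    df = data.loc[data["roi"] == roi].reset_index(drop=True)
    if df.empty:
        raise KeyError(f"no records for ROI {roi!r}")
    counts = df.groupby("subject_id")["month"].nunique()
    if (counts < 2).any():
        raise ValueError("every subject needs >= 2 distinct time points")

    if method == "ols":
        return _ols_fit(df, roi, groups)
    if method != "lmm":
        raise ValueError("method must be 'lmm' or 'ols'")

    exog = _design(df, groups)
    # groups absent from the sample leave all-zero dummy columns; drop them
    # for fitting and report zero coefficients
    active = [c for c in exog.columns if c == "intercept" or exog[c].abs().sum() > 0]
    exog_fit = exog[active]
    y = df["value"].to_numpy(dtype=float)
    subj = df["subject_id"].to_numpy()
    exog_re = exog[["intercept", "month"]].to_numpy()

    def _try(reml: bool, slope: bool):
        re = exog_re if slope else exog_re[:, :1]
        model = sm.MixedLM(y, exog_fit.to_numpy(), groups=subj, exog_re=re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(reml=reml, method=["lbfgs", "powell"], maxiter=500)

    fallback = None
    singular = False
    res = None
    try:
        res = _try(reml=True, slope=True)
        if not res.converged:
            raise RuntimeError("REML did not converge")
    except Exception:
        try:
            res = _try(reml=False, slope=True)
            fallback = "ml"
            if not res.converged:
                raise RuntimeError("ML did not converge")
        except Exception:
            res = _try(reml=False, slope=False)
            fallback = "intercept_only"

    slope_model = fallback != "intercept_only"
    cov_re = np.asarray(res.cov_re)
    if slope_model:
        if cov_re.shape != (2, 2):
            cov_re = np.pad(cov_re, ((0, 2 - cov_re.shape[0]), (0, 2 - cov_re.shape[1])))
        if cov_re[1, 1] <= 1e-12 * max(1.0, cov_re[0, 0]):
            singular = True
    else:
        cov_re = np.array([[float(cov_re[0, 0]), 0.0], [0.0, 0.0]])
        singular = True

    re_frame = pd.DataFrame(res.random_effects).T
    intercepts = re_frame.iloc[:, 0]
    if slope_model and re_frame.shape[1] > 1:
        slopes = re_frame.iloc[:, 1]
    else:
        slopes = pd.Series(0.0, index=re_frame.index)

    # Zero-residual limit: when the estimated noise variance is numerically
    # zero each subject's line is observed exactly and the conditional modes
    # converge to the per-subject OLS fit of the fixed-effect residuals;
    # compute that limit directly instead of trusting boundary shrinkage.
    if slope_model and res.scale <= 1e-8 * max(np.var(y), 1e-30):
        fe_resid = y - exog_fit.to_numpy() @ np.asarray(res.fe_params)
        ints, slps = {}, {}
        t_all = df["month"].to_numpy(dtype=float)
        for sid in re_frame.index:
            rows = subj == sid
            A = np.column_stack([np.ones(rows.sum()), t_all[rows]])
            coef, *_ = np.linalg.lstsq(A, fe_resid[rows], rcond=None)
            ints[sid], slps[sid] = coef[0], coef[1]
        intercepts = pd.Series(ints)
        slopes = pd.Series(slps)

    fixed = pd.Series(0.0, index=_FIXED_NAMES)
    fixed[active] = np.asarray(res.fe_params)
    fixed_se = pd.Series(np.nan, index=_FIXED_NAMES)
    fixed_se[active] = np.asarray(res.bse_fe)
    return ROIMixedModelFit(
        roi=roi,
        fixed_effects=fixed,
        fixed_se=fixed_se,
        cov_re=cov_re,
        sigma2=float(res.scale),
        random_slopes=slopes,
        random_intercepts=intercepts,
        converged=bool(res.converged),
        singular=singular,
        fallback=fallback,
    )


def predict_rates(
    fits: dict[str, ROIMixedModelFit] | list[ROIMixedModelFit],
    groups: pd.Series | dict,
) -> pd.DataFrame:
    """Subjects x ROI matrix of predicted per-month rates of change.

    rate[i, j] = b3j + b4j*MCI_i + b5j*AD_i + gamma2_ij_hat
    """
    if isinstance(fits, list):
        fits = {f.roi: f for f in fits}
    groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    out = {}
    for roi, fit in fits.items():
        missing = [s for s in groups.index if s not in fit.random_slopes.index]
        if missing:
            raise KeyError(
                f"subjects missing from fit of {roi!r}: {missing[:5]}"
            )
        fixed = groups.map(fit.group_slope)
        out[roi] = fixed + fit.random_slopes.reindex(groups.index)
    return pd.DataFrame(out, index=groups.index)


class ROIRateModel:
    """Estimator wrapper: fit every ROI's mixed model, predict rate matrix.

    Parameters
    ----------
    method : "lmm" or "ols"

    Attributes (after fit)
    ----------------------
    fits_ : dict roi -> ROIMixedModelFit
    rates_ : DataFrame subjects x ROIs of predicted rates (per month)
    """

    def __init__(self, method: str = "lmm"):
        self.method = method

    def get_params(self, deep: bool = True) -> dict:
        return {"method": self.method}

    def set_params(self, **params) -> "ROIRateModel":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, data: pd.DataFrame, groups: pd.Series | dict) -> "ROIRateModel":
        groups = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
        self.fits_ = {
            roi: fit_roi_lmm(data, roi, groups, method=self.method)
            for roi in pd.unique(data["roi"])
        }
        self.rates_ = predict_rates(self.fits_, groups)
        self.groups_ = groups
        return self

    def predict(self, groups: pd.Series | dict | None = None) -> pd.DataFrame:
        if groups is None:
            return self.rates_
        return predict_rates(self.fits_, groups)


def qq_normality_check(
    fits: dict[str, ROIMixedModelFit], alpha: float = 0.01, min_n: int = 10
) -> pd.DataFrame:
    """Shapiro-Wilk check of the predicted random slopes, per ROI.

    Advisory: flags ROIs whose conditional modes look non-Gaussian and
    returns the ordered (theoretical, sample) quantile pairs for Q-Q
    plotting.
    """
    rows = []
    for roi, fit in fits.items():
        g2 = fit.random_slopes.to_numpy(dtype=float)
        g2 = g2[np.isfinite(g2)]
        if g2.size < min_n:
            rows.append(
                {"roi": roi, "n": g2.size, "statistic": np.nan, "p_value": np.nan,
                 "flagged": False, "note": "insufficient data"}
            )
            continue
        stat, p = stats.shapiro(g2)
        rows.append(
            {"roi": roi, "n": g2.size, "statistic": float(stat), "p_value": float(p),
             "flagged": bool(p < alpha), "note": ""}
        )
    return pd.DataFrame(rows)
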