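"""Inverse probability weights for the biased case-control sampling design.

Diagnostic groups are sampled out of proportion to their population
prevalence, so each subject in group D receives weight proportional to
p_D / n_D (assumed prevalence over sampled count), standardized so the
per-subject weights sum to the sample size n.  With prevalences summing
to one this gives w_D = n * p_D / n_D.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import GROUPS
from .datatypes import PrevalenceSpec, WeightVector

__all__ = ["derive_prevalence_ad", "compute_weights"]


def derive_prevalence_ad(
    n_ad: float, frac_over_55: float, total_pop: float
) -> float:
    """Approximate disease prevalence among the over-55 population.

    n_ad / (frac_over_55 * total_pop), rounded to the nearest multiple of
    0.005 (half a percent), ties away from zero.
    """
    if n_ad <= 0 or total_pop <= 0:
        raise ValueError("counts must be positive")
    if not (0.0 < frac_over_55 < 1.0):
        raise ValueError("frac_over_55 must lie in (0, 1)")
    raw = n_ad / (frac_over_55 * total_pop)
    # round half away from zero on the 0.005 grid
    units = raw / 0.005
    rounded = math.floor(units + 0.5) if units >= 0 else math.ceil(units - 0.5)
    return rounded * 0.005


def compute_weights(
    prevalence: PrevalenceSpec | dict[str, float],
    counts: dict[str, int],
    groups: pd.Series | np.ndarray | None = None,
) -> WeightVector:
    """Standardized inverse probability weights per diagnostic group.

    Parameters
    ----------
    prevalence : assumed population prevalences per group
    counts : sampled subject count per group
    groups : optional per-subject group labels; when omitted, a label
        vector is expanded from ``counts`` (group blocks in CN, MCI, AD
        order), which suffices when only the group weights matter.
    """
    if isinstance(prevalence, PrevalenceSpec):
        prev = prevalence.as_dict()
    else:
        prev = dict(prevalence)
        total = sum(prev.values())
        prev = {g: p / total for g, p in prev.items()}  # normalization invariance
    for g in GROUPS:
        if counts.get(g, 0) <= 0:
            if prev.get(g, 0) > 0:
                raise ValueError(f"group {g} has prevalence > 0 but no sampled subjects")
    n = sum(counts.values())
    raw = {g: prev[g] / counts[g] for g in GROUPS}
    scale = n / sum(counts[g] * raw[g] for g in GROUPS)
    group_weights = {g: raw[g] * scale for g in GROUPS}

    if groups is None:
        groups = np.concatenate([np.repeat(g, counts[g]) for g in GROUPS])
    groups = np.asarray(groups)
    weights = np.array([group_weights[g] for g in groups], dtype=float)
    return WeightVector(weights=weights, group_weights=group_weights, groups=groups)
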