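"""Core in-memory containers shared across the pipeline.

Genotypes are stored as minor-allele counts (0/1/2) in a float array with
``nan`` marking missing calls, alongside a per-SNP annotation frame.  The
containers are deliberately light: downstream stages operate on plain numpy
arrays and pandas frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns every SNP annotation frame carries
SNP_ANNOTATION_COLUMNS = ["snp_id", "chrom", "bp", "minor_allele", "major_allele", "region"]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs matrix of minor-allele counts.

    Parameters
    ----------
    values : ndarray of shape (n_subjects, n_snps)
        Minor-allele counts in {0, 1, 2}; ``nan`` encodes a missing call.
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id`` (unique), ``chrom`` (int),
        ``bp`` (1-based physical position), ``minor_allele``,
        ``major_allele`` and ``region`` (linkage-region label or None).
    subject_ids : list of str
        Unique subject identifiers, aligned with the rows of ``values``.
    """

    values: np.ndarray
    snps: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-dimensional")
        if len(self.subject_ids) != self.values.shape[0]:
            raise ValueError("subject_ids length does not match rows of values")
        if len(self.snps) != self.values.shape[1]:
            raise ValueError("snp annotation length does not match columns of values")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
            raise ValueError("genotype values must be in {0, 1, 2} or missing")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        if (np.asarray(self.snps["bp"]) <= 0).any():
            raise ValueError("bp positions must be positive (1-based)")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return np.isfinite(self.values).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Sample minor-allele frequency per SNP, ignoring missing calls.

        Computed as half the mean count; counts code the designated minor
        allele, so values above 0.5 indicate the designation is stale for
        this subject subset.
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / 2.0

    def select_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            raise ValueError("mask must be boolean")
        return GenotypeMatrix(
            values=self.values[:, mask],
            snps=self.snps.loc[mask].reset_index(drop=True),
            subject_ids=list(self.subject_ids),
        )

    def select_subjects(self, ids: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(self.values[rows], self.snps.copy(), list(ids))


@dataclass
class LinkageRegionTable:
    """Autosomal linkage regions on the Mb scale (closed intervals)."""

    table: pd.DataFrame  # columns: chrom, band, start_mb, end_mb

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "band", "start_mb", "end_mb"}
        if not required.issubset(t.columns):
            raise ValueError(f"region table needs columns {sorted(required)}")
        if (t["start_mb"] >= t["end_mb"]).any():
            raise ValueError("region start_mb must be < end_mb")
        if not t["chrom"].isin(range(1, 23)).all():
            raise ValueError("region chromosomes must be autosomal (1..22)")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        return [
            f"{int(r.chrom)}{r.band}" for r in self.table.itertuples()
        ]


@dataclass
class AncestryCoordinates:
    """Principal coordinates from classical MDS on an IBS distance matrix."""

    coords: np.ndarray          # subjects x d, columns ordered by eigenvalue
    eigenvalues: np.ndarray     # the d leading eigenvalues (descending)
    explained_fraction: float   # positive-eigenvalue mass captured by the d axes
    subject_ids: list[str] | None = None

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


@dataclass
class PrevalenceSpec:
    """Assumed population prevalences for the three diagnostic groups."""

    p_cn: float
    p_mci: float
    p_ad: float

    def __post_init__(self) -> None:
        probs = (self.p_cn, self.p_mci, self.p_ad)
        if not all(0.0 < p < 1.0 for p in probs):
            raise ValueError("prevalences must lie in (0, 1)")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {"CN": self.p_cn, "MCI": self.p_mci, "AD": self.p_ad}


@dataclass
class WeightVector:
    """Per-subject inverse probability weights, standardized to sum to n."""

    weights: np.ndarray                  # per-subject, full precision
    group_weights: dict[str, float]      # shared weight per diagnostic group
    groups: np.ndarray                   # per-subject group labels

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")

    @property
    def n(self) -> int:
        return self.weights.size

    def rounded(self, decimals: int = 2) -> dict[str, float]:
        """Display version of the group weights (stored at full precision)."""
        return {g: round(w, decimals) for g, w in self.group_weights.items()}


@dataclass
class RVTestResult:
    """Observed (weighted) RV coefficient with its permutation null sample."""

    rv_observed: float
    permutation_draws: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


@dataclass
class SNPScoreVector:
    """Per-SNP contributions to the RV numerator over the phenotype block."""

    snp_ids: np.ndarray
    raw: np.ndarray          # sum over phenotypes of squared cross-covariances
    normalized: np.ndarray   # raw rescaled to mean 1

    def ranked(self) -> pd.DataFrame:
        order = np.argsort(-self.normalized, kind="stable")
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids[order],
                "raw": self.raw[order],
                "score": self.normalized[order],
            }
        ).reset_index(drop=True)


@dataclass
class RefinedSets:
    """Priority (VIP >= 0.5) and top-hit (VIP >= 0.9) SNP sets."""

    priority: list[str]
    top_hit: list[str]

    def __post_init__(self) -> None:
        if not set(self.top_hit).issubset(self.priority):
            raise ValueError("top-hit set must be contained in the priority set")


@dataclass
class TruthRecord:
    """Ground truth retained by the cohort simulator for recovery tests."""

    causal_snp_ids: list[str]
    causal_effects: np.ndarray            # slope effect per causal SNP
    subject_random_effects: np.ndarray    # subjects x q x 2 (intercept, slope)
    group_slopes: pd.DataFrame            # per ROI: beta3 (CN), beta4 (MCI delta), beta5 (AD delta)
    ancestry: np.ndarray = field(default=None)  # latent subject ancestry coordinates

    def __post_init__(self) -> None:
        if len(self.causal_snp_ids) != np.asarray(self.causal_effects).size:
            raise ValueError("causal ids and effects must align")
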