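"""Genotype QC, linkage-region restriction, ancestry coordinates and LD.

The stages here turn raw minor-allele counts into the analysis-ready
matrix: drop SNPs failing call-rate / MAF / Hardy-Weinberg filters,
restrict to autosomal linkage regions, fill sporadic missing calls, and
derive ancestry principal coordinates from the identity-by-state (IBS)
distance matrix via classical multidimensional scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import AncestryCoordinates, GenotypeMatrix, LinkageRegionTable

__all__ = [
    "qc_filter",
    "hwe_exact_pvalue",
    "restrict_to_regions",
    "fill_missing",
    "ibs_distance",
    "ClassicalMDS",
    "mds_coordinates",
    "ld_r2",
    "ld_blocks",
]


@dataclass
class QCReport:
    """Counts of SNPs dropped by each filter, in application order."""

    n_input: int
    dropped_call_rate: int
    dropped_maf: int
    dropped_hwe: int
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": ["call_rate", "maf", "hwe"],
                "dropped": [self.dropped_call_rate, self.dropped_maf, self.dropped_hwe],
            }
        )


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the probabilities of tables no more probable
    than the observed one (two-sided by probability ordering).

    Parameters are genotype counts: ``n_aa`` homozygous major, ``n_ab``
    heterozygous, ``n_bb`` homozygous minor.
    """
    for c in (n_aa, n_ab, n_bb):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("at least one genotype count must be positive")
    n_minor = 2 * n_bb + n_ab
    n_major = 2 * n_aa + n_ab
    rare = min(n_minor, n_major)

    # P(n_het | allele counts) on the log scale, over all feasible het counts
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def log_prob(h: np.ndarray) -> np.ndarray:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            gammaln(n + 1)
            - gammaln(hom_rare + 1)
            - gammaln(h + 1)
            - gammaln(hom_common + 1)
            + h * np.log(2.0)
            + gammaln(rare + 1)
            + gammaln(2 * n - rare + 1)
            - gammaln(2 * n + 1)
        )

    logp = log_prob(hets)
    logp -= np.logaddexp.reduce(logp)  # renormalize for numerical safety
    probs = np.exp(logp)
    observed = probs[hets == n_ab][0]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def qc_filter(
    g: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    hwe_subjects: list[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply call-rate, MAF and HWE filters, in that fixed order.

    ``hwe_subjects`` designates the reference subgroup for the HWE test
    (e.g. cognitively normal subjects); default is all retained subjects.
    """
    if g.n_snps == 0:
        raise ValueError("empty genotype matrix")

    keep = np.ones(g.n_snps, dtype=bool)

    call = g.call_rate()
    fail_call = call < call_rate_min
    dropped_call = int(fail_call.sum())
    keep &= ~fail_call

    maf = g.maf()
    maf = np.minimum(maf, 1.0 - maf)  # guard against stale minor designation
    fail_maf = keep & ((maf < maf_min) | ~np.isfinite(maf))
    dropped_maf = int(fail_maf.sum())
    keep &= ~fail_maf

    if hwe_subjects is not None:
        sub = g.select_subjects(hwe_subjects)
    else:
        sub = g
    dropped_hwe = 0
    for k in np.flatnonzero(keep):
        col = sub.values[:, k]
        col = col[np.isfinite(col)]
        counts = [(col == c).sum() for c in (0, 1, 2)]
        if sum(counts) == 0:
            continue
        if hwe_exact_pvalue(*counts) < hwe_alpha:
            keep[k] = False
            dropped_hwe += 1

    if not keep.any():
        raise ValueError("all SNPs removed by QC filters")

    report = QCReport(
        n_input=g.n_snps,
        dropped_call_rate=dropped_call,
        dropped_maf=dropped_maf,
        dropped_hwe=dropped_hwe,
        n_retained=int(keep.sum()),
    )
    return g.select_snps(keep), report


def restrict_to_regions(
    g: GenotypeMatrix, regions: LinkageRegionTable
) -> GenotypeMatrix:
    """Keep SNPs inside the linkage regions (closed Mb intervals, autosomes).

    A retained SNP's ``region`` annotation is set to the matching region
    label (chromosome + band).
    """
    chrom = g.snps["chrom"].to_numpy()
    bp = g.snps["bp"].to_numpy()
    keep = np.zeros(g.n_snps, dtype=bool)
    label = np.array([None] * g.n_snps, dtype=object)
    for row, lab in zip(regions.table.itertuples(), regions.labels):
        lo = int(round(row.start_mb * 1e6))
        hi = int(round(row.end_mb * 1e6))
        inside = (chrom == row.chrom) & (bp >= lo) & (bp <= hi)
        label[inside & ~keep] = lab
        keep |= inside
    out = g.select_snps(keep)
    out.snps = out.snps.assign(region=label[keep])
    return out


def fill_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the SNP's rounded within-sample mean count."""
    values = g.values.copy()
    missing = ~np.isfinite(values)
    if missing.all(axis=0).any():
        raise ValueError("a SNP has no observed calls (should fail call-rate QC)")
    if missing.any():
        with np.errstate(invalid="ignore"):
            fills = np.round(np.nanmean(values, axis=0))
        values[missing] = np.broadcast_to(fills, values.shape)[missing]
    return GenotypeMatrix(values=values, snps=g.snps.copy(), subject_ids=list(g.subject_ids))


def ibs_distance(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Pairwise identity-by-state distance between subjects.

    D[i, j] = 1 - (1 / 2m) * sum_k (2 - |g_ik - g_jk|); 0 for identical
    genotype vectors, 1 for subjects homozygous for opposite alleles at
    every SNP.  Requires complete genotypes.
    """
    values = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    if values.shape[1] == 0:
        raise ValueError("no SNPs")
    if not np.isfinite(values).all():
        raise ValueError("missing genotypes; run fill_missing first")
    m = values.shape[1]
    # |g_i - g_j| summed over SNPs, via expansion on the 3-valued counts
    diff = np.abs(values[:, None, :] - values[None, :, :]).sum(axis=2)
    d = diff / (2.0 * m)
    np.fill_diagonal(d, 0.0)
    return d


class ClassicalMDS(BaseEstimator, TransformerMixin):
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centers ``-D**2 / 2`` and embeds with the top ``n_components``
    eigenvectors scaled by the square root of their eigenvalues.  Used to
    derive ancestry principal coordinates from the IBS distance matrix.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, n_components)
    eigenvalues_ : the leading eigenvalues, descending
    explained_fraction_ : positive-eigenvalue mass captured
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        D = np.asarray(X, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        eigval, eigvec = np.linalg.eigh(B)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]

        d = self.n_components
        pos_total = eigval[eigval > 0].sum()
        rank = int((eigval > max(1e-10, 1e-12 * abs(eigval[0]))).sum())
        if d > rank:
            warnings.warn(
                f"requested {d} coordinates but centered Gram rank is {rank}; "
                "padding with zero columns"
            )
        take = min(d, rank)
        coords = eigvec[:, :take] * np.sqrt(np.maximum(eigval[:take], 0.0))
        # sign convention: largest-magnitude loading positive
        for j in range(take):
            k = np.argmax(np.abs(coords[:, j]))
            if coords[k, j] < 0:
                coords[:, j] = -coords[:, j]
        if take < d:
            coords = np.hstack([coords, np.zeros((n, d - take))])
        self.embedding_ = coords
        self.eigenvalues_ = np.concatenate([eigval[:take], np.zeros(d - take)])
        self.explained_fraction_ = (
            float(eigval[:take].sum() / pos_total) if pos_total > 0 else 0.0
        )
        return coords


def mds_coordinates(
    D: np.ndarray, d: int = 10, subject_ids: list[str] | None = None
) -> AncestryCoordinates:
    """Functional wrapper over :class:`ClassicalMDS`."""
    mds = ClassicalMDS(n_components=d)
    coords = mds.fit_transform(D)
    return AncestryCoordinates(
        coords=coords,
        eigenvalues=mds.eigenvalues_,
        explained_fraction=mds.explained_fraction_,
        subject_ids=subject_ids,
    )


def _snp_column(g: GenotypeMatrix, snp) -> np.ndarray:
    if isinstance(snp, str):
        idx = np.flatnonzero(g.snp_ids == snp)
        if idx.size == 0:
            raise KeyError(f"unknown SNP id {snp!r}")
        snp = int(idx[0])
    return g.values[:, snp]


def ld_r2(
    g: GenotypeMatrix,
    i,
    j,
    subjects: list[str] | None = None,
) -> float:
    """Squared Pearson correlation between two SNPs' allele counts.

    ``subjects`` restricts the evaluation subset (conventionally the
    cognitively normal subjects); default is all subjects.
    """
    sub = g.select_subjects(subjects) if subjects is not None else g
    x = _snp_column(sub, i)
    y = _snp_column(sub, j)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("monomorphic SNP in the evaluation subset; r^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_blocks(
    g: GenotypeMatrix,
    snp_subset: list[str] | None = None,
    r2_min: float = 0.7,
    subjects: list[str] | None = None,
) -> dict[str, int]:
    """Group SNPs into LD blocks where every pair has r^2 > ``r2_min``.

    Greedy and deterministic: seed each block with the left-most (by bp)
    unassigned SNP, then scan the remaining SNPs in bp order, admitting
    one only if its r^2 with *all* current members exceeds the threshold.
    Singletons receive no label.

    Returns a mapping snp_id -> block number (1-based, in bp order of the
    block seeds).
    """
    ids = list(snp_subset) if snp_subset is not None else list(g.snp_ids)
    sub = g.select_subjects(subjects) if subjects is not None else g
    ann = sub.snps.set_index("snp_id")
    order = sorted(ids, key=lambda s: (ann.loc[s, "chrom"], ann.loc[s, "bp"]))

    cols = {s: _snp_column(sub, s) for s in order}

    def pair_r2(a: str, b: str) -> float:
        x, y = cols[a], cols[b]
        ok = np.isfinite(x) & np.isfinite(y)
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            return 0.0
        r = np.corrcoef(x[ok], y[ok])[0, 1]
        return float(r * r)

    assigned: dict[str, int] = {}
    block_no = 0
    for seed_pos, seed in enumerate(order):
        if seed in assigned:
            continue
        members = [seed]
        for cand in order[seed_pos + 1 :]:
            if cand in assigned:
                continue
            if ann.loc[cand, "chrom"] != ann.loc[seed, "chrom"]:
                continue
            if all(pair_r2(cand, m) > r2_min for m in members):
                members.append(cand)
        if len(members) > 1:
            block_no += 1
            for m in members:
                assigned[m] = block_no
    return assigned
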