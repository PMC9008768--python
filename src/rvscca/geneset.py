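"""Gene-level summaries of exclusion probabilities and maxmean set tests.

Variable exclusion probabilities (VEP = 1 - VIP) play the role p-values
usually play in gene-set software: each gene is summarized by the
second-smallest VEP among its SNPs (guarding against long genes
accumulating a spuriously extreme minimum), gene scores are mapped to
z-scores via -Phi^{-1}(VEP), and gene sets are tested with the
Efron-Tibshirani maxmean statistic, restandardized against random gene
sets of the same size.  Empirical set p-values come from re-running the
refinement under phenotype permutation, with Benjamini-Hochberg control
at a liberal FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneMap",
    "read_gmt",
    "gene_scores",
    "vep_to_z",
    "maxmean_set_statistic",
    "geneset_permutation",
]


@dataclass
class GeneMap:
    """Gene intervals (1-based, closed) with symmetric bp padding.

    A SNP maps to a gene when they share a chromosome and
    start - padding <= bp <= end + padding; the mapping is many-to-many.
    """

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end
    padding: int = 20_000

    def __post_init__(self) -> None:
        g = self.genes
        required = {"gene_id", "chrom", "start", "end"}
        if not required.issubset(g.columns):
            raise ValueError(f"gene map needs columns {sorted(required)}")
        if (g["start"] > g["end"]).any():
            raise ValueError("gene start must be <= end")
        if g["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")

    def assign_snps(self, snps: pd.DataFrame) -> dict[str, list[str]]:
        """gene_id -> list of snp_ids falling in the padded interval."""
        out: dict[str, list[str]] = {}
        for gene in self.genes.itertuples():
            lo = gene.start - self.padding
            hi = gene.end + self.padding
            hit = snps.loc[
                (snps["chrom"] == gene.chrom)
                & (snps["bp"] >= lo)
                & (snps["bp"] <= hi),
                "snp_id",
            ]
            out[gene.gene_id] = list(hit)
        return out


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set file: set name, description, then member gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def gene_scores(
    vep: pd.Series, snps: pd.DataFrame, gene_map: GeneMap
) -> pd.DataFrame:
    """Second-smallest VEP per gene (single-SNP genes fall back to their
    only VEP, flagged); genes without mapped SNPs are excluded."""
    assignment = gene_map.assign_snps(snps)
    rows = []
    for gene_id, snp_ids in assignment.items():
        vals = vep.reindex(snp_ids).dropna().sort_values()
        if vals.empty:
            continue
        if len(vals) >= 2:
            score, fallback = float(vals.iloc[1]), False
        else:
            score, fallback = float(vals.iloc[0]), True
        rows.append(
            {"gene_id": gene_id, "score": score, "n_snps": len(vals),
             "single_snp_fallback": fallback}
        )
    return pd.DataFrame(rows)


def vep_to_z(vep: np.ndarray, n_bootstrap: int) -> np.ndarray:
    """Map exclusion probabilities to z-scores: small VEP -> large z.

    VEPs are clipped to [1/(2B), 1 - 1/(2B)] before the probit transform
    so that 0 and 1 (possible at finite B) stay finite.
    """
    eps = 1.0 / (2.0 * n_bootstrap)
    clipped = np.clip(np.asarray(vep, dtype=float), eps, 1.0 - eps)
    return -stats.norm.ppf(clipped)


def _maxmean_raw(z: np.ndarray) -> float:
    pos = np.maximum(z, 0.0)
    neg = np.maximum(-z, 0.0)
    return float(max(pos.mean(), neg.mean()))


def maxmean_set_statistic(
    gene_z: pd.Series,
    set_genes: list[str],
    n_random: int = 1000,
    seed: int | None = None,
    restandardize: bool = True,
    reference: str = "random_sets",
) -> tuple[float, float]:
    """Maxmean statistic of a gene set, optionally restandardized.

    ``gene_z`` holds the z-transformed score of every gene in the
    universe.  The raw maxmean is max(mean(z+), mean(z-)) over the set;
    restandardization centers and scales it by the mean and standard
    deviation of the same statistic over random same-size gene draws
    (``reference="random_sets"``) or over the per-gene statistic of the
    whole universe (``reference="all_genes"``).

    Returns (raw, restandardized); the second equals the first when
    ``restandardize`` is False.
    """
    members = gene_z.reindex(set_genes).dropna()
    if members.empty:
        raise ValueError("gene set has no scored members")
    raw = _maxmean_raw(members.to_numpy())
    if not restandardize:
        return raw, raw

    universe = gene_z.to_numpy()
    k = len(members)
    if k >= gene_z.size:
        raise ValueError(
            "restandardization degenerate: the set spans the whole gene universe"
        )
    if reference == "all_genes":
        singles = np.array([_maxmean_raw(universe[[i]]) for i in range(universe.size)])
        mu, sd = singles.mean(), singles.std(ddof=1) / np.sqrt(k)
    elif reference == "random_sets":
        rng = np.random.default_rng(seed)
        draws = np.array(
            [
                _maxmean_raw(universe[rng.choice(universe.size, size=k, replace=False)])
                for _ in range(n_random)
            ]
        )
        mu, sd = draws.mean(), draws.std(ddof=1)
    else:
        raise ValueError("reference must be 'random_sets' or 'all_genes'")
    if sd == 0:
        return raw, 0.0
    return raw, (raw - mu) / sd


def geneset_permutation(
    observed_vep: pd.Series,
    null_vep_sampler,
    snps: pd.DataFrame,
    gene_map: GeneMap,
    gene_sets: dict[str, list[str]],
    n_bootstrap: int,
    n_perm: int = 100,
    fdr_cut: float = 0.8,
    seed: int | None = None,
    restandardize: bool = True,
) -> pd.DataFrame:
    """Permutation test of gene-set enrichment on VEP summaries.

    ``null_vep_sampler(rng)`` must return one per-SNP VEP Series drawn
    under the no-association null (the refinement recomputed on
    phenotype-permuted data, typically at a scaled-down bootstrap count).
    Empirical add-one p-values per set are Benjamini-Hochberg adjusted;
    candidate sets have adjusted p <= ``fdr_cut``.
    """
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    rng = np.random.default_rng(seed)

    def set_stats(vep: pd.Series, perm_seed) -> dict[str, float]:
        gs = gene_scores(vep, snps, gene_map)
        z = pd.Series(
            vep_to_z(gs["score"].to_numpy(), n_bootstrap), index=gs["gene_id"]
        )
        out = {}
        for name, genes in gene_sets.items():
            try:
                _, val = maxmean_set_statistic(
                    z, genes, seed=perm_seed, restandardize=restandardize
                )
            except ValueError:
                val = np.nan
            out[name] = val
        return out

    observed = set_stats(observed_vep, rng.integers(2**31))
    null = {name: np.empty(n_perm) for name in gene_sets}
    for b in range(n_perm):
        vep_b = null_vep_sampler(rng)
        stats_b = set_stats(vep_b, rng.integers(2**31))
        for name in gene_sets:
            null[name][b] = stats_b[name]

    rows = []
    for name in gene_sets:
        obs = observed[name]
        draws = null[name][np.isfinite(null[name])]
        if not np.isfinite(obs) or draws.size == 0:
            rows.append({"set": name, "maxmean": obs, "p_value": np.nan})
            continue
        p = (1.0 + (draws >= obs).sum()) / (1.0 + draws.size)
        rows.append({"set": name, "maxmean": obs, "p_value": p})
    result = pd.DataFrame(rows)
    ok = result["p_value"].notna()
    adjusted = np.full(len(result), np.nan)
    if ok.any():
        adjusted[ok.to_numpy()] = multipletests(
            result.loc[ok, "p_value"], method="fdr_bh"
        )[1]
    result["p_adjusted"] = adjusted
    result["candidate"] = result["p_adjusted"] <= fdr_cut
    return result
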