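"""Synthetic imaging-genetics cohorts with known ground truth.

The generator produces, from one integer seed, everything the analysis
pipeline consumes: a genotype matrix with LD-block structure inside
labelled linkage regions, longitudinal ROI trajectories following a
random-intercept / random-slope model, a covariate table (diagnostic
group, APOE genotype) and a :class:`~rvscca.datatypes.TruthRecord`.

Genotype model
--------------
Each SNP's two allele copies come from latent standard Gaussians
thresholded at the MAF-matched quantile ``Phi^{-1}(maf)``; SNPs inside
an LD block share one MAF (as tightly linked variants do) and an
exchangeable latent correlation *calibrated* so that the induced
haplotype-indicator correlation equals the configured ``rho`` — i.e.
``rho`` directly controls the genotype correlation (pairwise genotype
r^2 ~ rho^2), undoing the attenuation dichotomization would otherwise
introduce.  Between blocks the latents are independent.  A latent ancestry coordinate shifts the
threshold (hence the allele frequency) of every SNP, and also shifts ROI
baselines, so the ancestry-adjustment stage downstream has a real
confounder to remove.  These distributional choices are stand-ins: the
generative law of real genotypes is of course unknown.

Phenotype model
---------------
For subject i, ROI j and visit month t:

    Y_ijt = b0j + b1j*MCI + b2j*AD + (b3j + b4j*MCI + b5j*AD)*t
            + gamma1_ij + gamma2_ij * t + sum_k theta_k g_ik * t + eps_ijt

with gamma1 ~ N(0, s2_int), gamma2 ~ N(0, s2_slope), eps ~ N(0, s2_noise)
and theta_k nonzero only for the causal SNPs (all ROIs share the causal
slope contribution, an intentionally simple pleiotropy pattern).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import APOE_CATEGORIES, GROUPS, SimulationConfig
from .datatypes import GenotypeMatrix, TruthRecord

__all__ = ["simulate_genotypes", "simulate_cohort"]

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


def _snp_annotations(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay SNPs down in bp order inside their configured regions."""
    rows = []
    k = 0
    for spec in config.block_spec:
        # evenly spread positions with jitter, preserving order within region
        m = spec.n_snps
        span = spec.end_bp - spec.start_bp
        base = np.linspace(spec.start_bp, spec.end_bp, m + 2)[1:-1]
        jitter = rng.integers(-span // (4 * m + 4), span // (4 * m + 4) + 1, size=m)
        bps = np.sort(base.astype(np.int64) + jitter)
        block_id = 0
        offset = 0
        for size in spec.block_sizes:
            for j in range(size):
                minor, major = _ALLELE_PAIRS[(k + j) % len(_ALLELE_PAIRS)]
                rows.append(
                    {
                        "snp_id": f"rs{100000 + k + j}",
                        "chrom": spec.chrom,
                        "bp": int(bps[offset + j]),
                        "minor_allele": minor,
                        "major_allele": major,
                        "region": spec.region,
                        "sim_block": f"{spec.region}:{block_id}",
                    }
                )
            offset += size
            k += size
            block_id += 1
    return pd.DataFrame(rows)


def _calibrated_latent_rho(rho: float, maf: float) -> float:
    """Latent Gaussian correlation inducing indicator correlation ``rho``.

    Solves P(Z1 < z, Z2 < z; t) = maf^2 + rho * maf * (1 - maf) for the
    latent correlation t, with z = Phi^{-1}(maf), so that thresholding at
    the MAF quantile yields allele indicators with correlation rho.
    """
    if rho <= 0.0:
        return 0.0
    z = stats.norm.ppf(maf)
    target = maf**2 + rho * maf * (1.0 - maf)

    def orthant(t: float) -> float:
        return stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, t], [t, 1.0]]
        ).cdf([z, z])

    from scipy.optimize import brentq

    hi = 1.0 - 1e-9
    if orthant(hi) <= target:
        return hi
    return float(brentq(lambda t: orthant(t) - target, rho * 0.5, hi, xtol=1e-8))


def _latent_haplotypes(
    config: SimulationConfig,
    n: int,
    block_mafs: list[tuple[int, float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Two latent Gaussian sheets (n x n_snps x 2) with block correlation.

    ``block_mafs`` lists (block size, maf, rho) per block in column order;
    the latent exchangeable correlation is calibrated per block so the
    induced allele-indicator correlation equals rho.
    """
    z = np.empty((n, config.n_snps, 2))
    col = 0
    for size, maf, rho in block_mafs:
        t = _calibrated_latent_rho(rho, maf)
        shared = rng.standard_normal((n, 1, 2))
        own = rng.standard_normal((n, size, 2))
        z[:, col : col + size, :] = np.sqrt(t) * shared + np.sqrt(1.0 - t) * own
        col += size
    return z


def simulate_genotypes(
    config: SimulationConfig,
    *,
    ancestry: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw a subjects x n_snps matrix of minor-allele counts.

    Parameters
    ----------
    config : SimulationConfig
    ancestry : ndarray of shape (n_subjects, n_ancestry_dims), optional
        Latent ancestry coordinates; the first coordinate shifts each SNP's
        thresholding quantile by ``ancestry_maf_shift * loading``, creating
        allele-frequency stratification.  Omitted -> no stratification.
    rng : numpy Generator, optional
        Supply to embed this draw into a larger seeded simulation; default
        derives a dedicated stream from ``config.seed``.
    """
    if rng is None:
        rng = config.rng_streams("genotypes")["genotypes"]
    n = config.n_subjects
    snps = _snp_annotations(config, rng)
    # one MAF per LD block, shared by its SNPs
    block_mafs: list[tuple[int, float, float]] = []
    mafs = np.empty(config.n_snps)
    col = 0
    for spec in config.block_spec:
        for size in spec.block_sizes:
            m = float(rng.uniform(*config.maf_range))
            block_mafs.append((size, m, spec.rho))
            mafs[col : col + size] = m
            col += size
    z = _latent_haplotypes(config, n, block_mafs, rng)

    # MAF-matched thresholds; ancestry moves them per subject
    thresh = stats.norm.ppf(mafs)[None, :]  # 1 x p
    if ancestry is not None and config.ancestry_maf_shift != 0.0:
        loadings = rng.uniform(-1.0, 1.0, size=config.n_snps)
        shift = config.ancestry_maf_shift * np.outer(ancestry[:, 0], loadings)
        thresh = thresh + shift  # n x p
    counts = (z[:, :, 0] < thresh).astype(float) + (z[:, :, 1] < thresh).astype(float)

    if config.missing_rate > 0.0:
        mask = rng.random(counts.shape) < config.missing_rate
        counts[mask] = np.nan

    snps = snps.assign(true_maf=mafs)
    subject_ids = [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(values=counts, snps=snps, subject_ids=subject_ids)


def _draw_apoe(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    cats = list(APOE_CATEGORIES)
    probs = np.array([config.apoe_freqs[c] for c in cats])
    return rng.choice(cats, size=n, p=probs / probs.sum())


def _e4_count(apoe: np.ndarray) -> np.ndarray:
    return np.array([g.count("e4") for g in apoe], dtype=float)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate one full cohort.

    Returns
    -------
    genotypes : GenotypeMatrix
    phenotypes : DataFrame with columns (subject_id, roi, month, value) —
        long format, one row per retained visit measurement
    covariates : DataFrame with columns (subject_id, group, apoe)
    truth : TruthRecord
    """
    streams = config.rng_streams(
        "genotypes", "ancestry", "apoe", "effects", "trajectories", "dropout", "causal"
    )
    n = config.n_subjects
    q = config.q_rois
    groups = np.concatenate(
        [np.repeat(g, config.n_per_group[g]) for g in GROUPS]
    )

    ancestry = streams["ancestry"].standard_normal((n, config.n_ancestry_dims))
    genotypes = simulate_genotypes(config, ancestry=ancestry, rng=streams["genotypes"])
    apoe = _draw_apoe(config, n, streams["apoe"])

    causal_rng = streams["causal"]
    causal_idx = np.sort(
        causal_rng.choice(config.n_snps, size=config.n_causal, replace=False)
    )
    signs = causal_rng.choice([-1.0, 1.0], size=config.n_causal)
    causal_effects = config.effect_size * signs

    s2_int, s2_slope, s2_noise = config.variance_components
    eff_rng = streams["effects"]
    gamma1 = np.sqrt(s2_int) * eff_rng.standard_normal((n, q))
    gamma2 = np.sqrt(s2_slope) * eff_rng.standard_normal((n, q))

    # per-ROI fixed effects: baseline + group offsets + group slopes
    beta0 = config.baseline_mean + 0.2 * eff_rng.standard_normal(q)
    beta1 = -0.02 + 0.01 * eff_rng.standard_normal(q)   # MCI baseline offset
    beta2 = -0.05 + 0.01 * eff_rng.standard_normal(q)   # AD baseline offset
    beta3 = config.group_slopes["CN"] + 2.0e-4 * eff_rng.standard_normal(q)
    beta4 = (config.group_slopes["MCI"] - config.group_slopes["CN"]) + 2.0e-4 * eff_rng.standard_normal(q)
    beta5 = (config.group_slopes["AD"] - config.group_slopes["CN"]) + 2.0e-4 * eff_rng.standard_normal(q)

    mci = (groups == "MCI").astype(float)
    ad = (groups == "AD").astype(float)

    g_filled = np.nan_to_num(genotypes.values, nan=0.0)
    causal_slope = g_filled[:, causal_idx] @ causal_effects  # per subject, mm/month

    # confounding shifts on baseline level
    baseline_shift = (
        config.ancestry_baseline_shift * ancestry[:, 0]
        + config.apoe_baseline_shift * _e4_count(apoe)
    )

    months = np.asarray(config.visit_months, dtype=float)
    traj_rng = streams["trajectories"]
    drop_rng = streams["dropout"]
    records = []
    subject_ids = genotypes.subject_ids
    for i in range(n):
        intercepts = beta0 + beta1 * mci[i] + beta2 * ad[i] + gamma1[i] + baseline_shift[i]
        slopes = (
            beta3 + beta4 * mci[i] + beta5 * ad[i] + gamma2[i] + causal_slope[i]
        )
        noise = (
            np.sqrt(s2_noise) * traj_rng.standard_normal((months.size, q))
            if s2_noise > 0
            else np.zeros((months.size, q))
        )
        # baseline always kept; guarantee at least one follow-up
        keep = np.ones(months.size, dtype=bool)
        if config.dropout_prob > 0 and months.size > 2:
            keep[1:] = drop_rng.random(months.size - 1) >= config.dropout_prob
            if not keep[1:].any():
                keep[int(drop_rng.integers(1, months.size))] = True
        for ti, t in enumerate(months):
            if not keep[ti]:
                continue
            values = intercepts + slopes * t + noise[ti]
            for j in range(q):
                records.append((subject_ids[i], f"roi{j:02d}", t, values[j]))

    phenotypes = pd.DataFrame(records, columns=["subject_id", "roi", "month", "value"])
    covariates = pd.DataFrame(
        {"subject_id": subject_ids, "group": groups, "apoe": apoe}
    )
    truth = TruthRecord(
        causal_snp_ids=list(genotypes.snp_ids[causal_idx]),
        causal_effects=causal_effects,
        subject_random_effects=np.stack([gamma1, gamma2], axis=-1),
        group_slopes=pd.DataFrame(
            {
                "roi": [f"roi{j:02d}" for j in range(q)],
                "beta0": beta0,
                "beta3": beta3,
                "beta4": beta4,
                "beta5": beta5,
            }
        ),
        ancestry=ancestry,
    )
    return genotypes, phenotypes, covariates, truth
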