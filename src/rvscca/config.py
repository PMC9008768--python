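"""Simulation configuration for the synthetic imaging-genetics cohort.

The defaults emulate the design of a two-phase AD case-control imaging
study: three diagnostic groups (CN / MCI / AD) sampled disproportionately
to their population prevalences, SNPs organised into LD blocks inside
labelled linkage regions, and 56 ROI trajectories observed at months
0, 6, 12, 18 and 24 under a random-intercept / random-slope model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

GROUPS = ("CN", "MCI", "AD")

#: APOE genotype categories (epsilon-allele pairs)
APOE_CATEGORIES = ("e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4")

# Hardy-Weinberg-ish frequencies for allele freqs (e2, e3, e4) ~ (0.08, 0.78, 0.14)
_DEFAULT_APOE_FREQS = {
    "e2e2": 0.006,
    "e2e3": 0.125,
    "e2e4": 0.022,
    "e3e3": 0.608,
    "e3e4": 0.219,
    "e4e4": 0.020,
}


@dataclass
class BlockSpec:
    """One labelled linkage region holding LD blocks of SNPs.

    ``block_sizes`` lists the number of SNPs in each LD block inside the
    region; ``rho`` is the exchangeable within-block correlation of the
    latent haplotype Gaussians (rho = 0 gives independent SNPs).
    """

    region: str
    chrom: int
    start_bp: int
    end_bp: int
    block_sizes: list[int]
    rho: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.start_bp >= self.end_bp:
            raise ValueError("start_bp must be < end_bp")
        if any(b < 1 for b in self.block_sizes):
            raise ValueError("block sizes must be positive")

    @property
    def n_snps(self) -> int:
        return int(sum(self.block_sizes))


def _default_blocks() -> list[BlockSpec]:
    # Two labelled regions (bands echo the Alzgene-style naming convention),
    # mixed block sizes, moderately strong within-block LD.
    return [
        BlockSpec("6p21.1-q15", 6, 43_000_000, 91_000_000, [5, 5, 5, 5, 5, 5], 0.85),
        BlockSpec("10p14-q24", 10, 10_000_000, 100_000_000, [5, 5, 5, 5, 5, 5], 0.85),
    ]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    Units: visit times in months; ROI measurements on a cortical-thickness
    scale (mm); ``effect_size`` in mm per month per minor allele.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"CN": 60, "MCI": 90, "AD": 50}
    )
    population_prevalence: dict[str, float] = field(
        default_factory=lambda: {"CN": 0.875, "MCI": 0.05, "AD": 0.075}
    )
    n_snps: int = 60
    block_spec: list[BlockSpec] = field(default_factory=_default_blocks)
    maf_range: tuple[float, float] = (0.1, 0.4)
    n_causal: int = 10
    effect_size: float = 2.0e-3
    q_rois: int = 56
    visit_months: tuple[int, ...] = (0, 6, 12, 18, 24)
    variance_components: tuple[float, float, float] = (0.25**2, 2.0e-3**2, 0.05**2)
    dropout_prob: float = 0.1
    missing_rate: float = 0.0
    n_ancestry_dims: int = 2
    ancestry_maf_shift: float = 0.3
    ancestry_baseline_shift: float = 0.1
    apoe_freqs: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_APOE_FREQS))
    apoe_baseline_shift: float = -0.05
    group_slopes: dict[str, float] = field(
        default_factory=lambda: {"CN": -1.0e-3, "MCI": -3.0e-3, "AD": -5.0e-3}
    )
    baseline_mean: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_per_group) != set(GROUPS):
            raise ValueError(f"n_per_group must have keys {GROUPS}")
        if set(self.population_prevalence) != set(GROUPS):
            raise ValueError(f"population_prevalence must have keys {GROUPS}")
        prev = np.array([self.population_prevalence[g] for g in GROUPS])
        if abs(prev.sum() - 1.0) > 1e-9:
            raise ValueError("population prevalences must sum to 1")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0.05, 0.5]")
        total = sum(b.n_snps for b in self.block_spec)
        if total != self.n_snps:
            raise ValueError(
                f"block sizes sum to {total} but n_snps = {self.n_snps}"
            )
        if any(v <= 0 for v in self.variance_components):
            raise ValueError("variance components must be positive")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ValueError("dropout_prob must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        freq_sum = sum(self.apoe_freqs.values())
        if abs(freq_sum - 1.0) > 1e-6:
            raise ValueError("APOE genotype frequencies must sum to 1")

    # Zero residual / slope variance is meaningful for exactness checks, so
    # a separate constructor relaxes positivity to nonnegativity.
    @classmethod
    def noiseless(cls, **kwargs) -> "SimulationConfig":
        """Build a config allowing zero variance components (exact-linearity runs)."""
        vc = kwargs.pop("variance_components", (0.25**2, 0.0, 0.0))
        if any(v < 0 for v in vc):
            raise ValueError("variance components must be nonnegative")
        cfg = cls(**{**kwargs, "variance_components": (1.0, 1.0, 1.0)})
        cfg.variance_components = tuple(vc)
        return cfg

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group.values()))

    def rng_streams(self, *labels: str) -> dict[str, np.random.Generator]:
        """Named child generators split off the master seed.

        One global seed drives every sub-generator through
        ``numpy.random.SeedSequence.spawn``-style keyed children, so adding a
        stream never perturbs the draws of the others.
        """
        return {
            lab: np.random.default_rng(
                np.random.SeedSequence(
                    entropy=self.seed, spawn_key=(zlib.crc32(lab.encode()),)
                )
            )
            for lab in labels
        }

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "block_spec" in raw:
            raw["block_spec"] = [BlockSpec(**b) for b in raw["block_spec"]]
        for key in ("maf_range", "visit_months", "variance_components"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
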