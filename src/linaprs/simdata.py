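"""Synthetic cohort generation.

Generates genotype/phenotype cohorts with the statistical structure the
multi-task PRS method assumes:

* biallelic SNPs in Hardy-Weinberg proportions at MAFs drawn uniformly from
  a configurable range (independent SNPs by default; an optional
  block-exchangeable LD mode correlates SNPs within blocks via a Gaussian
  copula on the underlying alleles);
* sparse additive liabilities per trait under the liability-threshold model,
  with a tunable fraction of each trait's causal SNPs drawn from a common
  pleiotropic pool (shared genetic basis across traits);
* low-prevalence binary outcomes obtained by thresholding the liability at
  the standard-normal quantile of 1 - prevalence;
* decoy SNPs sampled i.i.d. per subject from each real SNP's *empirical*
  genotype distribution, hence frequency-matched but trait-independent.

All generators are bit-reproducible given the config seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genio import GenotypeDataset, PhenotypeMatrix

__all__ = [
    "SimConfig",
    "EffectMatrix",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_cohort",
    "make_decoys",
    "standardize_genotypes",
]

_AUTOSOMES = [str(c) for c in range(1, 23)]


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults describe the package's reference desk-scale cohort: 4000
    subjects, 300 SNPs, 8 rare binary traits at 5% prevalence, 20 causal
    SNPs per trait of which 80% come from a shared pleiotropic pool, and
    liability heritability 0.5.
    """

    n_subjects: int = 4000
    n_snps: int = 300
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 8
    n_causal_per_trait: int = 20
    shared_fraction: float = 0.8
    heritability: float = 0.5
    prevalences: float | Sequence[float] = 0.05
    seed: int = 0
    ld_block_size: int = 1  # 1 = independent SNPs
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_subjects <= 0 or self.n_snps <= 0:
            raise ValueError("n_subjects and n_snps must be positive")
        if self.n_causal_per_trait > self.n_snps:
            raise ValueError("n_causal_per_trait cannot exceed n_snps")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0, 1]")
        if not (0.0 <= self.heritability < 1.0):
            raise ValueError("heritability must be in [0, 1)")
        prev = self.prevalence_vector()
        if not ((prev > 0) & (prev < 1)).all():
            raise ValueError("prevalences must be in (0, 1)")

    def prevalence_vector(self) -> np.ndarray:
        prev = np.asarray(self.prevalences, dtype=float)
        if prev.ndim == 0:
            prev = np.full(self.n_traits, float(prev))
        if prev.shape != (self.n_traits,):
            raise ValueError("prevalences must be scalar or length n_traits")
        return prev

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["prevalences"] = (
            float(self.prevalences)
            if np.ndim(self.prevalences) == 0
            else [float(p) for p in self.prevalences]
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


@dataclass
class EffectMatrix:
    """Ground-truth liability effects: ``betas`` is traits x SNPs (per
    standardized genotype); ``causal_mask`` marks the nonzero entries."""

    betas: np.ndarray
    causal_mask: np.ndarray

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.causal_mask = np.asarray(self.causal_mask, dtype=bool)
        if self.betas.shape != self.causal_mask.shape:
            raise ValueError("betas and causal_mask shapes differ")
        if (self.betas[~self.causal_mask] != 0).any():
            raise ValueError("betas must be zero off the causal mask")


def simulate_genotypes(config: SimConfig) -> GenotypeDataset:
    """Sample HWE genotypes: minor-allele count ~ Binomial(2, p_j), encoded
    ``2 - count`` so that 0 = homozygous minor."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_subjects, config.n_snps
    mafs = rng.uniform(*config.maf_range, size=m)
    if config.ld_block_size > 1 and config.ld_rho > 0:
        counts = _ld_block_allele_counts(rng, n, mafs, config.ld_block_size, config.ld_rho)
    else:
        counts = rng.binomial(2, mafs, size=(n, m))
    geno = (2 - counts).astype(np.int8)
    alleles = np.array([("A", "B")] * m, dtype=object)
    return GenotypeDataset(
        genotypes=geno,
        snp_ids=np.array([f"snp{j}" for j in range(m)], dtype=object),
        chromosomes=np.array([_AUTOSOMES[j % 22] for j in range(m)], dtype=object),
        positions=np.arange(1, m + 1) * 1000,
        alleles=alleles,
        sample_ids=np.array([f"subj{i}" for i in range(n)], dtype=object),
    )


def _ld_block_allele_counts(rng, n: int, mafs: np.ndarray, block: int, rho: float) -> np.ndarray:
    """Gaussian-copula haplotypes: within a block, the two allele draws of
    each subject share a block factor with correlation ``rho``."""
    m = len(mafs)
    counts = np.zeros((n, m), dtype=np.int64)
    thresholds = stats.norm.ppf(mafs)
    for hap in range(2):
        z = np.empty((n, m))
        for b0 in range(0, m, block):
            b1 = min(b0 + block, m)
            shared = rng.standard_normal((n, 1))
            own = rng.standard_normal((n, b1 - b0))
            z[:, b0:b1] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        counts += (z < thresholds).astype(np.int64)
    return counts


def simulate_effects(config: SimConfig) -> EffectMatrix:
    """Draw per-trait sparse causal sets with a shared pleiotropic pool.

    A pool of ``round(shared_fraction * n_causal_per_trait)`` SNPs is drawn
    once; every trait takes the whole pool plus private causal SNPs drawn
    from the remainder.  Nonzero effects are Gaussian and then rescaled per
    trait so the genetic liability variance is exactly ``heritability``.
    """
    rng = np.random.default_rng(config.seed + 1)
    d, m, k = config.n_traits, config.n_snps, config.n_causal_per_trait
    n_shared = int(round(config.shared_fraction * k))
    if n_shared > m:
        raise ValueError("shared pool larger than the SNP panel")
    pool = rng.choice(m, size=n_shared, replace=False)
    rest = np.setdiff1d(np.arange(m), pool)
    if k - n_shared > len(rest):
        raise ValueError("not enough non-pool SNPs for private causal sets")
    mask = np.zeros((d, m), dtype=bool)
    for t in range(d):
        private = rng.choice(rest, size=k - n_shared, replace=False)
        mask[t, pool] = True
        mask[t, private] = True
    betas = np.zeros((d, m))
    h2 = config.heritability
    for t in range(d):
        raw = rng.normal(0.0, np.sqrt(h2 / k) if h2 > 0 else 1.0, size=k)
        if h2 > 0:
            raw *= np.sqrt(h2 / np.sum(raw**2))
        else:
            raw[:] = 0.0
        betas[t, mask[t]] = raw
    return EffectMatrix(betas=betas, causal_mask=mask)


def standardize_genotypes(genotypes: np.ndarray) -> np.ndarray:
    """Column-standardize a genotype matrix (zero mean, unit sd; monomorphic
    columns map to zero)."""
    X = np.asarray(genotypes, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def simulate_phenotypes(
    genotypes: GenotypeDataset, effects: EffectMatrix, config: SimConfig
) -> PhenotypeMatrix:
    """Liability-threshold outcomes.

    L_t = sum_j beta_tj z_j + eps_t, eps_t ~ N(0, 1 - h2), z the standardized
    genotype; a subject is a case for trait t iff L_t exceeds the
    standard-normal quantile of 1 - prevalence_t.
    """
    if effects.betas.shape[1] != genotypes.n_snps:
        raise ValueError("effects and genotypes have different SNP counts")
    rng = np.random.default_rng(config.seed + 2)
    Z = standardize_genotypes(genotypes.genotypes)
    genetic = Z @ effects.betas.T
    noise = rng.normal(0.0, np.sqrt(1.0 - config.heritability), size=genetic.shape)
    liability = genetic + noise
    prev = config.prevalence_vector()
    thresholds = stats.norm.ppf(1.0 - prev)
    outcomes = (liability > thresholds).astype(np.int8)
    names = [f"trait{t}" for t in range(config.n_traits)]
    return PhenotypeMatrix.from_outcomes(outcomes, names, genotypes.sample_ids)


def simulate_cohort(config: SimConfig) -> tuple[GenotypeDataset, EffectMatrix, PhenotypeMatrix]:
    """Convenience wrapper: genotypes, ground-truth effects, phenotypes."""
    geno = simulate_genotypes(config)
    eff = simulate_effects(config)
    phen = simulate_phenotypes(geno, eff, config)
    return geno, eff, phen


def make_decoys(genotypes: GenotypeDataset, seed: int) -> GenotypeDataset:
    """Append one decoy per real SNP, doubling the panel.

    Decoy j is sampled i.i.d. per subject from real SNP j's *empirical*
    genotype proportions, so it matches the real SNP's homozygous-minor /
    heterozygous / homozygous-major frequencies in expectation while being
    independent of every trait.  Decoys inherit the paired SNP's chromosome
    label (so downstream sex-chromosome filtering treats them alike).
    """
    if genotypes.is_decoy.any():
        raise ValueError("dataset already contains decoy SNPs")
    rng = np.random.default_rng(seed)
    n, m = genotypes.genotypes.shape
    decoy = np.empty((n, m), dtype=np.int8)
    for j in range(m):
        counts = np.bincount(genotypes.genotypes[:, j], minlength=3).astype(float)
        decoy[:, j] = rng.choice(3, size=n, p=counts / counts.sum())
    return GenotypeDataset(
        genotypes=np.concatenate([genotypes.genotypes, decoy], axis=1),
        snp_ids=np.concatenate([genotypes.snp_ids,
                                np.array([f"decoy_{s}" for s in genotypes.snp_ids], dtype=object)]),
        chromosomes=np.concatenate([genotypes.chromosomes, genotypes.chromosomes]),
        positions=np.concatenate([genotypes.positions, genotypes.positions]),
        alleles=np.concatenate([genotypes.alleles, genotypes.alleles], axis=0),
        sample_ids=genotypes.sample_ids,
        is_decoy=np.concatenate([np.zeros(m, dtype=bool), np.ones(m, dtype=bool)]),
    )
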