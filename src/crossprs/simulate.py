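"""Synthetic multi-population GWAS data with known truth.

Emulates the ingredients the joint model consumes: per-population genotype
panels with block LD and population-specific allele frequencies, correlated
spike-and-slab causal effects, phenotypes with exactly realized heritability,
and marginal-regression summary statistics.  Genotypes come from a latent
Gaussian threshold model: within each block of ``block_size`` SNPs, each
haplotype's latent vector follows a stationary AR(ld_decay) process and is
thresholded at the allele-frequency quantile; two haplotypes sum to 0/1/2
dosages.  Blocks are independent, which matches the independent-LD-block
assumption of the sampler.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DomainError
from .sumstats import SumStatsTable, write_dosage_matrix

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "compute_sumstats",
    "make_fixture",
    "binarize_liability",
]

_POP_NAMES = ("EUR", "EAS", "AFR", "SAS", "AMR")


def _default_rho(K: int) -> np.ndarray:
    """Correlation defaults: rho12=0.6, rho23=0.8, rho13=0.5 (then 0.6)."""
    R = np.eye(K)
    named = {(0, 1): 0.6, (1, 2): 0.8, (0, 2): 0.5}
    for i in range(K - 1):
        for j in range(i + 1, K):
            R[i, j] = R[j, i] = named.get((i, j), 0.6)
    return R


@dataclass
class SimConfig:
    """Study design for one synthetic dataset.

    Defaults mirror the simulation design the method was assessed under:
    three populations with 4:2:1 training sizes, 5000-individual validation
    and testing sets, per-population heritability 0.3, causal-effect
    correlations (0.6, 0.8, 0.5), and causal proportion p in
    {0.005, 0.05, 0.5}.  ``desk()`` gives a two-population scaled-down
    version suitable for test runs.
    """

    K: int = 3
    S: int = 30000
    n_train: tuple = (40000, 20000, 10000)
    n_valid: int = 5000
    n_test: int = 5000
    p_causal: float = 0.05
    h2: float | Sequence[float] = 0.3
    rho: np.ndarray | None = None
    maf_range: tuple = (0.05, 0.5)
    ld_decay: float | Sequence[float] = (0.9, 0.85, 0.8)
    block_size: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho is None:
            self.rho = _default_rho(self.K)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.shape != (self.K, self.K):
            raise DomainError("rho must be K x K")
        if not np.allclose(self.rho, self.rho.T) or not np.allclose(np.diag(self.rho), 1.0):
            raise DomainError("rho must be symmetric with unit diagonal")
        if np.min(np.linalg.eigvalsh(self.rho)) < -1e-10:
            raise DomainError("rho must be positive semi-definite")
        if not (0.0 <= self.p_causal <= 1.0):
            raise DomainError("p_causal must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise DomainError("maf_range must satisfy 0 < low <= high <= 0.5")
        if len(self.n_train) < self.K:
            raise DomainError("n_train must give one size per population")

    @property
    def h2_vec(self) -> np.ndarray:
        h = np.broadcast_to(np.asarray(self.h2, dtype=float), (self.K,))
        if np.any((h < 0) | (h >= 1)):
            raise DomainError("h2 must lie in [0, 1)")
        return np.array(h)

    @property
    def ld_decay_vec(self) -> np.ndarray:
        d = np.asarray(self.ld_decay, dtype=float)
        if d.ndim == 0:
            d = np.full(self.K, float(d))
        return d[: self.K]

    @property
    def population_labels(self) -> list[str]:
        return [_POP_NAMES[k] if k < len(_POP_NAMES) else f"POP{k}" for k in range(self.K)]

    @classmethod
    def desk(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Two-population desk-scale preset (S=2000, train 8000/4000)."""
        kw = dict(
            K=2,
            S=2000,
            n_train=(8000, 4000),
            n_valid=2000,
            n_test=2000,
            p_causal=0.05,
            h2=0.3,
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class SimDataset:
    """Generated genotypes/phenotypes/summary statistics plus the truth."""

    config: SimConfig
    snp_id: np.ndarray
    genotypes: dict            # pop -> {"train"|"valid"|"test": (n, S) int8}
    phenotypes: dict           # pop -> {"train"|"valid"|"test": (n,) float}
    beta_true: np.ndarray      # (S, K) standardized-scale causal effects
    sumstats: list             # K SumStatsTable from the training partitions
    truth_record: dict = field(default_factory=dict)


def _pop_rng(config: SimConfig, name: str):
    key = zlib.crc32(name.encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(key,))
    )


def population_frequencies(config: SimConfig, population: int) -> np.ndarray:
    """Per-population allele frequencies, drawn once per population from the
    configured MAF range and shared across train/valid/test partitions."""
    rng = _pop_rng(config, f"maf:{population}")
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=config.S)


def simulate_genotypes(config: SimConfig, population: int, n: int, rng) -> np.ndarray:
    """Draw an (n, S) dosage matrix for one population.

    Latent AR(ld_decay) Gaussians within each block are thresholded per
    haplotype at the allele-frequency quantile; two independent haplotypes
    sum to the dosage.  Blocks are independent.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    freqs = population_frequencies(config, population)
    thresh = norm.ppf(freqs)
    phi = float(config.ld_decay_vec[population])
    out = np.empty((n, config.S), dtype=np.int8)
    innov_sd = np.sqrt(1.0 - phi * phi)
    for start in range(0, config.S, config.block_size):
        stop = min(start + config.block_size, config.S)
        m = stop - start
        dose = np.zeros((n, m), dtype=np.int8)
        for _hap in range(2):
            z = np.empty((n, m), dtype=np.float32)
            z[:, 0] = rng.standard_normal(n)
            eps = rng.standard_normal((n, m - 1)).astype(np.float32) if m > 1 else None
            for t in range(1, m):
                z[:, t] = phi * z[:, t - 1] + innov_sd * eps[:, t - 1]
            dose += (z < thresh[start:stop].astype(np.float32)).astype(np.int8)
        out[:, start:stop] = dose
    return out


def simulate_effects(config: SimConfig, rng) -> np.ndarray:
    """Spike-and-slab correlated effects.

    Each SNP is causal with probability p; causal rows are multivariate
    normal with per-population variance h_k^2 / (p * S) and cross-population
    correlation rho.  Non-causal rows are zero in every population.
    """
    S, K = config.S, config.K
    beta = np.zeros((S, K))
    if config.p_causal == 0.0:
        return beta
    causal = rng.random(S) < config.p_causal
    m = int(causal.sum())
    if m == 0:
        return beta
    h = np.sqrt(config.h2_vec)
    cov = np.outer(h, h) * config.rho / (config.p_causal * S)
    L = np.linalg.cholesky(cov + 1e-14 * np.eye(K))
    beta[causal] = rng.standard_normal((m, K)) @ L.T
    return beta


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def simulate_phenotypes(genotypes: np.ndarray, beta_true: np.ndarray, h2: float, rng) -> np.ndarray:
    """Phenotypes with exactly realized in-sample heritability.

    The genetic value g uses column-standardized genotypes; the noise is
    orthogonalized to g in-sample and scaled so var(g)/var(y) = h2 exactly.
    """
    n = genotypes.shape[0]
    g = _standardize_columns(genotypes) @ np.asarray(beta_true, dtype=float)
    eps = rng.standard_normal(n)
    eps -= eps.mean()
    if h2 == 0.0:
        return eps / eps.std()
    var_g = g.var()
    if var_g == 0.0:
        raise DomainError("no causal signal but h2 > 0")
    eps -= g * (eps @ g) / (g @ g)
    eps *= np.sqrt(var_g * (1.0 - h2) / h2 / eps.var())
    y = g + eps
    return y - y.mean()


def binarize_liability(y: np.ndarray, prevalence: float, rng=None) -> np.ndarray:
    """Case/control status by thresholding a liability at a prevalence."""
    if not (0.0 < prevalence < 1.0):
        raise DomainError("prevalence must lie in (0, 1)")
    cut = np.quantile(y, 1.0 - prevalence)
    return (y > cut).astype(int)


def compute_sumstats(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    population_label: str,
    snp_id: Sequence[str] | None = None,
) -> SumStatsTable:
    """Marginal-regression summary statistics on the standardized scale.

    Per SNP, the coefficient of standardized phenotype on the standardized
    dosage (the sample correlation); the standard-error convention on this
    scale is 1/sqrt(n).  Monomorphic SNPs are excluded (unavailable).
    """
    n, S = genotypes.shape
    if n <= 2:
        raise DomainError("need n > 2 individuals")
    if snp_id is None:
        snp_id = [f"rs{j + 1}" for j in range(S)]
    snp_id = np.asarray(snp_id, dtype=object)
    sd = np.asarray(genotypes, dtype=float).std(axis=0)
    poly = sd > 0.0
    Xs = _standardize_columns(genotypes[:, poly])
    y = np.asarray(phenotype, dtype=float)
    ys = (y - y.mean()) / y.std()
    beta_hat = Xs.T @ ys / n
    return SumStatsTable(
        population_label=population_label,
        snp_id=snp_id[poly],
        effect_allele=np.full(int(poly.sum()), "A", dtype=object),
        other_allele=np.full(int(poly.sum()), "G", dtype=object),
        beta_hat_std=beta_hat,
        sample_size=n,
        chromosome=np.ones(int(poly.sum()), dtype=int),
    )


def write_sumstats(table: SumStatsTable, path) -> None:
    """TSV round-trippable through read_sumstats (BETA on the standardized
    scale with the SE = 1/sqrt(N) convention)."""
    n = table.sample_size
    pd.DataFrame(
        {
            "SNP": table.snp_id,
            "A1": table.effect_allele,
            "A2": table.other_allele,
            "BETA": table.beta_hat_std,
            "SE": np.full(len(table), 1.0 / np.sqrt(n)),
            "N": np.full(len(table), n, dtype=int),
            "CHR": table.chromosome if table.chromosome is not None else 1,
        }
    ).to_csv(path, sep="\t", index=False)


def make_fixture(config: SimConfig, out_dir=None) -> SimDataset:
    """End-to-end generation for all populations and partitions.

    Training partitions yield summary statistics; the validation partition
    doubles as the LD reference; truth (causal indices, effects, realized
    heritability and effect correlations) is recorded.  When ``out_dir`` is
    given, writes sumstats/reference/phenotype files and a truth JSON.
    """
    labels = config.population_labels
    snp_id = np.asarray([f"rs{j + 1}" for j in range(config.S)], dtype=object)
    beta = simulate_effects(config, _pop_rng(config, "effects"))
    causal = np.flatnonzero(np.any(beta != 0.0, axis=1))

    genotypes: dict = {}
    phenotypes: dict = {}
    sumstats = []
    realized_h2 = []
    for k, pop in enumerate(labels):
        genotypes[pop] = {}
        phenotypes[pop] = {}
        sizes = {"train": config.n_train[k], "valid": config.n_valid, "test": config.n_test}
        for part, n in sizes.items():
            rng = _pop_rng(config, f"geno:{pop}:{part}")
            X = simulate_genotypes(config, k, n, rng)
            y = simulate_phenotypes(
                X, beta[:, k], float(config.h2_vec[k]), _pop_rng(config, f"pheno:{pop}:{part}")
            )
            genotypes[pop][part] = X
            phenotypes[pop][part] = y
        g = _standardize_columns(genotypes[pop]["train"]) @ beta[:, k]
        y = phenotypes[pop]["train"]
        realized_h2.append(float(g.var() / y.var()))
        sumstats.append(
            compute_sumstats(genotypes[pop]["train"], y, pop, snp_id=snp_id)
        )

    if len(causal) > 1 and config.K > 1:
        eff_corr = np.corrcoef(beta[causal].T)
    else:
        eff_corr = np.eye(config.K)
    truth = {
        "causal_indices": causal.tolist(),
        "realized_h2": realized_h2,
        "rho_config": config.rho.tolist(),
        "effect_correlation": np.asarray(eff_corr).tolist(),
        "seed": config.seed,
    }
    ds = SimDataset(
        config=config,
        snp_id=snp_id,
        genotypes=genotypes,
        phenotypes=phenotypes,
        beta_true=beta,
        sumstats=sumstats,
        truth_record=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, pop in enumerate(labels):
            write_sumstats(sumstats[k], out / f"sumstats_{pop}.tsv")
            write_dosage_matrix(out / f"ref_{pop}.tsv", snp_id, genotypes[pop]["valid"])
            for part in ("valid", "test"):
                write_dosage_matrix(
                    out / f"geno_{pop}_{part}.tsv", snp_id, genotypes[pop][part]
                )
                pd.DataFrame(
                    {
                        "IID": [f"{pop}_{part}_{i}" for i in range(len(phenotypes[pop][part]))],
                        "PHENO": phenotypes[pop][part],
                    }
                ).to_csv(out / f"pheno_{pop}_{part}.tsv", sep="\t", index=False)
        beta_out = {f"pop{k}": beta[causal, k].tolist() for k in range(config.K)}
        (out / "truth.json").write_text(
            json.dumps({**truth, "beta_true_causal": beta_out}, indent=1)
        )
    return ds
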