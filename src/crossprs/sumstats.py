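"""Reading, validation and harmonization of GWAS summary statistics.

Summary statistics arrive as one tab-separated table per population with
columns ``SNP, A1, A2, BETA`` (or ``OR``), ``SE, N`` and an optional ``CHR``.
Effects are converted to the standardized scale z/sqrt(N) on which the joint
model operates (standardized phenotype, column-standardized genotypes).
Harmonization aligns alleles across populations, removes strand-ambiguous
variants and records which SNP is available in which population in the
binary missingness matrix ``T`` (S x K).  LD is summarized per population as
independent block correlation matrices estimated from reference dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, FormatError

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

__all__ = [
    "SumStatsTable",
    "HarmonizedPanel",
    "LdBlock",
    "LdBlockSet",
    "read_sumstats",
    "effective_sample_size",
    "standardize_effects",
    "harmonize",
    "build_ld_blocks",
    "read_dosage_matrix",
    "write_dosage_matrix",
]


@dataclass
class SumStatsTable:
    """Per-population GWAS summary statistics on the standardized scale.

    ``beta_hat_std`` holds z/sqrt(N) per SNP; ``sample_size`` is the scalar
    GWAS sample size N_k (a per-SNP override is kept in ``n_per_snp`` when the
    input provides varying N).
    """

    population_label: str
    snp_id: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    beta_hat_std: np.ndarray
    sample_size: int
    is_binary: bool = False
    chromosome: np.ndarray | None = None
    n_per_snp: np.ndarray | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.beta_hat_std = np.asarray(self.beta_hat_std, dtype=float)
        if len(np.unique(self.snp_id)) != len(self.snp_id):
            raise FormatError(
                f"duplicate SNP ids in table for {self.population_label}"
            )
        if not np.all(np.isfinite(self.beta_hat_std)):
            raise FormatError("non-finite standardized effects")
        if int(self.sample_size) < 2:
            raise DomainError("sample_size must be >= 2")
        same = np.asarray(self.effect_allele) == np.asarray(self.other_allele)
        if np.any(same):
            raise FormatError("effect allele equals other allele for some SNPs")

    def __len__(self) -> int:
        return len(self.snp_id)


@dataclass
class HarmonizedPanel:
    """Allele-aligned multi-population summary statistics.

    ``T[j, k] = 1`` iff SNP j has statistics in population k; ``beta_hat`` is
    NaN-masked exactly where ``T = 0``.  Row order is deterministic
    (chromosome, then first appearance across the input tables).
    """

    snp_id: np.ndarray
    chromosome: np.ndarray
    populations: list[str]
    T: np.ndarray
    beta_hat: np.ndarray
    N: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    log: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    def beta_filled(self) -> np.ndarray:
        """beta_hat with masked entries replaced by exact zeros."""
        return np.where(self.T == 1, np.nan_to_num(self.beta_hat), 0.0)


@dataclass
class LdBlock:
    """One independent LD block of a single population.

    ``snp_indices`` index rows of the HarmonizedPanel (restricted to SNPs with
    T=1 in this population); ``D`` is the regularized reference correlation.
    """

    population_label: str
    block_index: int
    snp_indices: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=int)
        if np.any(np.diff(self.snp_indices) <= 0):
            raise FormatError("block snp_indices must be strictly increasing")
        if self.D.shape != (len(self.snp_indices),) * 2:
            raise FormatError("D shape inconsistent with snp_indices")


@dataclass
class LdBlockSet:
    """Per-population partition of available SNPs into LD blocks."""

    blocks: dict[str, list[LdBlock]]

    @property
    def L(self) -> dict[str, int]:
        return {pop: len(bl) for pop, bl in self.blocks.items()}

    def for_population(self, pop: str) -> list[LdBlock]:
        return self.blocks[pop]


def effective_sample_size(n_case: int, n_control: int) -> float:
    """Effective N for binary-trait summary statistics.

    Returns ``4 * n_case * n_control / (n_case + n_control)``, the quantity
    that replaces N when cases and controls are unbalanced.
    """
    if n_case < 1 or n_control < 1:
        raise DomainError("case/control counts must be positive")
    return 4.0 * n_case * n_control / (n_case + n_control)


def standardize_effects(beta, se, n) -> np.ndarray:
    """Convert marginal effects to the standardized scale z / sqrt(N).

    On this scale the marginal estimate is directly comparable to the
    standardized-genotype, standardized-phenotype regression coefficient the
    joint model assumes.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise DomainError("standard errors must be strictly positive")
    return (beta / se) / np.sqrt(np.asarray(n, dtype=float))


def read_sumstats(path, population_label: str, is_binary: bool = False) -> SumStatsTable:
    """Read one population's summary statistics from a tab-separated file.

    Required header columns: SNP, A1, A2, BETA (or OR), SE, N.  Optional CHR.
    Rows with missing or non-finite required fields are dropped and counted;
    odds ratios are moved to the log scale; duplicated SNP ids keep the first
    occurrence.
    """
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "A1": str, "A2": str})
    df.columns = [c.upper() for c in df.columns]
    for col in ("SNP", "A1", "A2", "SE", "N"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col}")
    if "BETA" in df.columns:
        effect_col = "BETA"
    elif "OR" in df.columns:
        effect_col = "OR"
    else:
        raise FormatError("missing required column BETA/OR")

    n_raw = len(df)
    required = ["SNP", "A1", "A2", effect_col, "SE", "N"]
    df = df.dropna(subset=required)
    for col in (effect_col, "SE", "N"):
        df = df[np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
    n_dropped = n_raw - len(df)

    dup_mask = df["SNP"].duplicated(keep="first")
    n_dup = int(dup_mask.sum())
    if n_dup:
        logger.warning("%s: removed %d duplicated SNP ids", population_label, n_dup)
        df = df[~dup_mask]
    if len(df) == 0:
        raise EmptyInputError(f"no usable rows in {path}")

    beta = pd.to_numeric(df[effect_col]).to_numpy(dtype=float)
    if effect_col == "OR":
        if np.any(beta <= 0):
            raise FormatError("OR values must be strictly positive")
        beta = np.log(beta)
    se = pd.to_numeric(df["SE"]).to_numpy(dtype=float)
    n_col = pd.to_numeric(df["N"]).to_numpy(dtype=float)
    beta_std = standardize_effects(beta, se, n_col)

    chrom = None
    if "CHR" in df.columns:
        chrom = pd.to_numeric(df["CHR"]).to_numpy(dtype=int)

    if n_dropped:
        logger.info("%s: dropped %d incomplete rows", population_label, n_dropped)

    return SumStatsTable(
        population_label=population_label,
        snp_id=df["SNP"].to_numpy(dtype=object),
        effect_allele=df["A1"].str.upper().to_numpy(dtype=object),
        other_allele=df["A2"].str.upper().to_numpy(dtype=object),
        beta_hat_std=beta_std,
        sample_size=int(round(float(np.median(n_col)))),
        is_binary=is_binary,
        chromosome=chrom,
        n_per_snp=n_col,
        log={"dropped_rows": n_dropped, "duplicates": n_dup},
    )


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(
    tables: Sequence[SumStatsTable],
    reference_snps: Sequence[str] | None = None,
) -> HarmonizedPanel:
    """Align K summary-statistic tables onto one SNP panel.

    The SNP universe is the union of table SNPs (intersected with
    ``reference_snps`` when given).  Alleles are aligned to the first
    population carrying each SNP; a swapped effect/other pair flips the sign
    of the standardized effect; strand-ambiguous (A/T, C/G) SNPs and SNPs
    whose alleles neither match nor swap in some population are removed.
    """
    if len(tables) == 0:
        raise EmptyInputError("no summary-statistic tables given")
    labels = [t.population_label for t in tables]
    if len(set(labels)) != len(labels):
        raise FormatError("population labels must be distinct")

    keep = set(map(str, reference_snps)) if reference_snps is not None else None

    # deterministic union: first-appearance order across tables
    order: list[str] = []
    seen: set[str] = set()
    for t in tables:
        for s in t.snp_id:
            if s not in seen and (keep is None or s in keep):
                seen.add(s)
                order.append(s)

    index = {s: j for j, s in enumerate(order)}
    S, K = len(order), len(tables)
    T = np.zeros((S, K), dtype=np.uint8)
    beta = np.full((S, K), np.nan)
    chrom = np.ones(S, dtype=int)
    a1 = np.empty(S, dtype=object)
    a2 = np.empty(S, dtype=object)
    anchored = np.zeros(S, dtype=bool)
    bad = np.zeros(S, dtype=bool)
    n_ambiguous = 0
    n_irreconcilable = 0

    for k, t in enumerate(tables):
        t_chrom = t.chromosome
        for i, s in enumerate(t.snp_id):
            j = index.get(s)
            if j is None:
                continue
            ea, oa = t.effect_allele[i], t.other_allele[i]
            if _is_ambiguous(ea, oa):
                if not bad[j]:
                    n_ambiguous += 1
                bad[j] = True
                continue
            b = t.beta_hat_std[i]
            if not anchored[j]:
                a1[j], a2[j] = ea, oa
                anchored[j] = True
                if t_chrom is not None:
                    chrom[j] = t_chrom[i]
            elif (ea, oa) == (a1[j], a2[j]):
                pass
            elif (ea, oa) == (a2[j], a1[j]):
                b = -b
            else:
                if not bad[j]:
                    n_irreconcilable += 1
                bad[j] = True
                continue
            T[j, k] = 1
            beta[j, k] = b

    keep_rows = anchored & ~bad & (T.sum(axis=1) >= 1)
    if not np.any(keep_rows):
        raise EmptyInputError("all SNPs removed during harmonization")
    if n_ambiguous:
        logger.info("removed %d strand-ambiguous SNPs", n_ambiguous)
    if n_irreconcilable:
        logger.warning("removed %d SNPs with irreconcilable alleles", n_irreconcilable)

    # stable sort by chromosome, preserving first-appearance order within
    rows = np.flatnonzero(keep_rows)
    rows = rows[np.argsort(chrom[rows], kind="stable")]
    return HarmonizedPanel(
        snp_id=np.asarray(order, dtype=object)[rows],
        chromosome=chrom[rows],
        populations=list(labels),
        T=T[rows],
        beta_hat=beta[rows],
        N=np.array([t.sample_size for t in tables], dtype=float),
        effect_allele=a1[rows],
        other_allele=a2[rows],
        log={"ambiguous": n_ambiguous, "irreconcilable": n_irreconcilable},
    )


def _regularized_corr(X: np.ndarray, ridge: float) -> np.ndarray:
    """Sample correlation of columns of X with a ridge, rescaled to unit diag."""
    C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    C = C + ridge * np.eye(C.shape[0])
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def build_ld_blocks(
    genotypes: Mapping[str, tuple[Sequence[str], np.ndarray]],
    panel: HarmonizedPanel,
    block_size: int = 250,
    ridge: float = 1e-3,
    boundaries: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> LdBlockSet:
    """Estimate per-population block correlation matrices from reference dosages.

    ``genotypes`` maps population label to ``(snp_ids, dosage matrix)`` with
    individuals in rows.  Within each population, consecutive available SNPs
    are grouped into blocks of at most ``block_size`` (or externally supplied
    half-open ``boundaries`` over that population's available-SNP sequence).
    Monomorphic reference SNPs are removed from that population's panel
    (T set to 0) and logged.
    """
    if block_size < 1:
        raise DomainError("block_size must be positive")
    if ridge < 0:
        raise DomainError("ridge must be nonnegative")
    blocks: dict[str, list[LdBlock]] = {}
    for k, pop in enumerate(panel.populations):
        ids, X = genotypes[pop]
        X = np.asarray(X, dtype=float)
        col = {s: c for c, s in enumerate(ids)}
        avail = np.flatnonzero(panel.T[:, k] == 1)
        missing = [j for j in avail if panel.snp_id[j] not in col]
        if missing:
            raise FormatError(
                f"{pop}: {len(missing)} panel SNPs absent from reference "
                f"(first: {panel.snp_id[missing[0]]})"
            )
        # drop monomorphic reference SNPs from this population
        keep = []
        n_mono = 0
        for j in avail:
            x = X[:, col[panel.snp_id[j]]]
            if np.std(x) == 0.0:
                panel.T[j, k] = 0
                panel.beta_hat[j, k] = np.nan
                n_mono += 1
            else:
                keep.append(j)
        if n_mono:
            logger.warning("%s: removed %d monomorphic reference SNPs", pop, n_mono)
        keep = np.asarray(keep, dtype=int)

        if boundaries is not None and pop in boundaries:
            spans = list(boundaries[pop])
        else:
            spans = [
                (s, min(s + block_size, len(keep)))
                for s in range(0, len(keep), block_size)
            ]
        pop_blocks = []
        for b, (lo, hi) in enumerate(spans):
            idx = keep[lo:hi]
            if len(idx) == 0:
                continue
            cols = [col[panel.snp_id[j]] for j in idx]
            D = _regularized_corr(X[:, cols], ridge)
            pop_blocks.append(LdBlock(pop, b, idx, D))
        covered = np.concatenate([bl.snp_indices for bl in pop_blocks]) if pop_blocks else np.array([], int)
        if sorted(covered.tolist()) != keep.tolist():
            raise FormatError(f"{pop}: block boundaries do not partition available SNPs")
        blocks[pop] = pop_blocks
    return LdBlockSet(blocks=blocks)


def read_dosage_matrix(path) -> tuple[list[str], np.ndarray]:
    """Read a plain dosage matrix: one header row of SNP ids, 0/1/2 rows below."""
    df = pd.read_csv(path, sep="\t")
    return list(df.columns), df.to_numpy(dtype=float)


def write_dosage_matrix(path, snp_ids: Sequence[str], X: np.ndarray) -> None:
    pd.DataFrame(np.asarray(X), columns=list(snp_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.0f"
    )
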