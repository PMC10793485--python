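"""Polygenic scores and the evaluation / tuning procedures.

Prediction accuracy for quantitative traits is the incremental variance
explained R^2 = 1 - SS1/SS0 between a covariates-only null model and the
full model adding the PRS; binary traits use the AUC of a logistic model's
fitted probabilities.  Tuning mirrors the two published strategies: pick the
best global-shrinkage value phi on a validation set ("best"), or linearly
combine the standardized per-population scores per phi and then pick phi
("linear"), with repeated random validation/test splits for stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .errors import DomainError, EmptyInputError

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "EvalResult",
    "CombinationModel",
    "compute_prs",
    "evaluate_r2",
    "evaluate_auc",
    "linear_combine",
    "select_phi",
    "split_evaluate",
    "relative_improvement",
]


@dataclass
class ScoreTable:
    """Per-individual scores, one column per (model, phi) combination."""

    individual_id: np.ndarray
    score: np.ndarray
    columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.score = np.atleast_2d(np.asarray(self.score, dtype=float))
        if self.score.shape[0] != len(self.individual_id):
            self.score = self.score.T
        if not np.all(np.isfinite(self.score)):
            raise DomainError("scores must be finite")


@dataclass
class EvalResult:
    metric_name: str
    value: float
    n_individuals: int
    covariates_used: list = field(default_factory=list)


@dataclass
class CombinationModel:
    """Validation-learned linear combination of standardized population scores."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    included: np.ndarray
    phi_selected: object = None

    def apply(self, scores: np.ndarray) -> np.ndarray:
        z = (scores[:, self.included] - self.means) / self.sds
        return z @ self.weights


def compute_prs(
    genotypes: np.ndarray,
    snp_ids: Sequence[str],
    weights: pd.DataFrame,
    genotype_alleles: Mapping[str, str] | None = None,
) -> np.ndarray:
    """Additive score: sum over SNPs of dosage times posterior weight.

    ``weights`` has columns SNP, A1, WEIGHT.  When ``genotype_alleles`` maps
    SNP id to the allele the dosage counts, dosages coded on the opposite
    allele are flipped (2 - dosage); otherwise coding is assumed to match.
    Missing dosages (NaN) are mean-imputed per SNP.
    """
    w = {str(r.SNP): (str(r.A1), float(r.WEIGHT)) for r in weights.itertuples()}
    X = np.asarray(genotypes, dtype=float)
    score = np.zeros(X.shape[0])
    overlap = 0
    for c, snp in enumerate(snp_ids):
        entry = w.get(str(snp))
        if entry is None:
            continue
        allele, weight = entry
        x = X[:, c]
        if np.any(np.isnan(x)):
            x = np.where(np.isnan(x), np.nanmean(x), x)
        if genotype_alleles is not None and genotype_alleles.get(str(snp), allele) != allele:
            x = 2.0 - x
        score += x * weight
        overlap += 1
    if overlap == 0:
        raise EmptyInputError("no overlap between genotype SNPs and weights")
    return score


def _design(n: int, covariates: np.ndarray | None, *extra) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.append(cov)
    cols.extend(np.asarray(e, dtype=float).reshape(n, -1) for e in extra)
    return np.column_stack(cols)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def evaluate_r2(
    phenotype: np.ndarray,
    prs: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] = (),
) -> EvalResult:
    """Incremental variance explained: R^2 = 1 - SS1/SS0.

    SS0 is the residual sum of squares of the covariates-only (null) model,
    SS1 of the full model adding the PRS.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if np.std(y) == 0.0:
        raise DomainError("constant phenotype: R^2 undefined")
    ss0 = _rss(y, _design(n, covariates))
    ss1 = _rss(y, _design(n, covariates, prs))
    return EvalResult("R2", 1.0 - ss1 / ss0, n, list(covariate_names))


def evaluate_auc(
    case_status: np.ndarray,
    prs: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: Sequence[str] = (),
) -> EvalResult:
    """AUC of the fitted probabilities of a logistic model (covariates + PRS).

    The AUC is the Mann-Whitney rank statistic with ties averaged.
    """
    y = np.asarray(case_status, dtype=int)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise DomainError("both classes must be present")
    X = _design(n, covariates, prs)[:, 1:]  # sklearn adds its own intercept
    model = LogisticRegression(C=np.inf, max_iter=2000)
    model.fit(X, y)
    prob = model.predict_proba(X)[:, 1]
    return EvalResult("AUC", float(roc_auc_score(y, prob)), n, list(covariate_names))


def linear_combine(
    valid_scores: np.ndarray,
    test_scores: np.ndarray,
    phenotype_valid: np.ndarray,
    covariates_valid: np.ndarray | None = None,
    include_covariates: bool = False,
) -> tuple[CombinationModel, np.ndarray]:
    """Learn a linear combination of standardized per-population scores.

    Each score column is standardized by its validation mean/sd; weights are
    least squares of the validation phenotype on the standardized scores
    (optionally alongside covariates, which do not enter the combined score).
    The identical standardization and weights are applied to the test scores.
    Zero-variance columns are dropped with a warning; collinearity resolves
    to the minimum-norm solution.
    """
    V = np.atleast_2d(np.asarray(valid_scores, dtype=float))
    Tst = np.atleast_2d(np.asarray(test_scores, dtype=float))
    y = np.asarray(phenotype_valid, dtype=float)
    if V.shape[0] != len(y):
        V = V.T
    if Tst.shape[1] != V.shape[1]:
        Tst = Tst.T
    if V.shape[0] < V.shape[1] + 2:
        raise DomainError("validation set too small for the combination fit")
    sds = V.std(axis=0)
    included = sds > 0.0
    if not np.all(included):
        logger.warning("dropping %d zero-variance score columns", int((~included).sum()))
    if not np.any(included):
        raise DomainError("all score columns have zero variance")
    means = V[:, included].mean(axis=0)
    sds = sds[included]
    Z = (V[:, included] - means) / sds
    design = _design(len(y), covariates_valid if include_covariates else None, Z)
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    w = coef[-Z.shape[1]:]
    model = CombinationModel(weights=w, means=means, sds=sds, included=included)
    return model, model.apply(Tst)


def select_phi(results_per_phi: Mapping) -> object:
    """Arg-max of the validation metric over the phi grid.

    Exact ties break toward "auto", then toward the larger numeric phi.
    """
    if len(results_per_phi) == 0:
        raise EmptyInputError("no phi candidates evaluated")
    best = max(results_per_phi.values())
    ties = [phi for phi, v in results_per_phi.items() if v == best]
    if "auto" in ties:
        return "auto"
    return max(ties)


def relative_improvement(metric_a: float, metric_b: float) -> float:
    """Percent improvement of A over B: (a - b) / b * 100."""
    if metric_b == 0:
        raise DomainError("reference metric is zero")
    return (metric_a - metric_b) / metric_b * 100.0


def _metric(y, score, covariates, binary):
    if binary:
        return evaluate_auc(y, score, covariates).value
    return evaluate_r2(y, score, covariates).value


def split_evaluate(
    scores,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    n_splits: int = 100,
    valid_fraction: float = 1.0 / 3.0,
    seed: int = 0,
    binary: bool = False,
    include_covariates_in_combination: bool = False,
) -> dict:
    """Repeated random validation/test splits with per-split tuning.

    ``scores`` is either a single score vector (tuning-free: the metric is
    simply evaluated on each test partition) or a mapping
    ``{phi: (n, K) score matrix}``; in the latter case each split learns a
    linear combination per phi on the validation third, selects phi by the
    validation metric, and evaluates the chosen combined score on the test
    two-thirds.  Returns median/min/max across splits plus per-split detail.
    """
    y = np.asarray(phenotype, dtype=float if not binary else int)
    n = len(y)
    if n_splits < 1:
        raise DomainError("n_splits must be >= 1")
    if not (0.0 < valid_fraction < 1.0):
        raise DomainError("valid_fraction must lie in (0, 1)")
    n_valid = int(round(n * valid_fraction))
    if n_valid < 3 or n - n_valid < 3:
        raise DomainError(f"split of {n} at fraction {valid_fraction} too small")
    rng = np.random.default_rng(seed)
    tuned = isinstance(scores, Mapping)
    values = []
    chosen = []
    for split in range(n_splits):
        perm = rng.permutation(n)
        vi, ti = perm[:n_valid], perm[n_valid:]
        cov_v = None if covariates is None else np.asarray(covariates)[vi]
        cov_t = None if covariates is None else np.asarray(covariates)[ti]
        if not tuned:
            s = np.asarray(scores, dtype=float)
            values.append(_metric(y[ti], s[ti], cov_t, binary))
            continue
        per_phi_metric = {}
        per_phi_test = {}
        for phi, mat in scores.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim == 1:
                mat = mat[:, None]
            model, test_score = linear_combine(
                mat[vi], mat[ti], y[vi], cov_v,
                include_covariates=include_covariates_in_combination,
            )
            valid_score = model.apply(mat[vi])
            per_phi_metric[phi] = _metric(y[vi], valid_score, cov_v, binary)
            per_phi_test[phi] = test_score
        phi_star = select_phi(per_phi_metric)
        chosen.append(phi_star)
        values.append(_metric(y[ti], per_phi_test[phi_star], cov_t, binary))
    values = np.asarray(values)
    out = {
        "median": float(np.median(values)),
        "min": float(values.min()),
        "max": float(values.max()),
        "values": values,
        "n_splits": n_splits,
    }
    if tuned:
        out["phi_selected"] = chosen
    return out
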