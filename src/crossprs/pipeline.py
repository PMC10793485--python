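"""High-level workflows composing the modules end to end.

These helpers wire a SimDataset (or files read through sumstats) into the
sampler and the evaluation layer: harmonize -> LD blocks -> chain ->
standardized per-population scores -> metrics.  The CLI and the acceptance
machinery are thin wrappers over these functions.
"""

from __future__ import annotations

import numpy as np

from .gibbs import McmcConfig, ModelHyper, PosteriorSummary, run_chain
from .simulate import SimDataset, _standardize_columns
from .sumstats import HarmonizedPanel, LdBlockSet, build_ld_blocks, harmonize

__all__ = [
    "panel_and_blocks",
    "fit_joint",
    "population_scores",
    "grid_fits",
]


def panel_and_blocks(
    dataset: SimDataset,
    block_size: int | None = None,
    ridge: float = 1e-3,
    ld_partition: str = "valid",
) -> tuple[HarmonizedPanel, LdBlockSet]:
    """Harmonize a dataset's summary statistics and build reference LD blocks.

    The LD reference defaults to the validation partition, matching the study
    design where the validation genotypes double as the reference panel.
    """
    panel = harmonize(dataset.sumstats)
    if block_size is None:
        block_size = dataset.config.block_size
    ref = {
        pop: (list(dataset.snp_id), dataset.genotypes[pop][ld_partition])
        for pop in panel.populations
    }
    blocks = build_ld_blocks(ref, panel, block_size=block_size, ridge=ridge)
    return panel, blocks


def fit_joint(
    panel: HarmonizedPanel,
    blocks: LdBlockSet,
    phi="auto",
    seed: int = 0,
    n_iter: int | None = None,
    n_burnin: int | None = None,
    cons: float = 0.99,
) -> PosteriorSummary:
    """Run one chain with phi either "auto" or a fixed grid value."""
    if phi == "auto":
        hyper = ModelHyper(phi_mode="auto")
    else:
        hyper = ModelHyper(phi_mode="fixed", phi_value=float(phi))
    config = McmcConfig(seed=seed, n_iter=n_iter, n_burnin=n_burnin, cons=cons)
    return run_chain(panel, blocks, hyper, config)


def population_scores(
    dataset: SimDataset,
    panel: HarmonizedPanel,
    summary: PosteriorSummary,
    target_pop: str,
    partition: str = "test",
) -> np.ndarray:
    """Scores of the target population's individuals under each population's
    posterior-mean effects: (n, K) matrix on standardized dosages.

    Column k is the PRS built from population k's effect estimates; the
    target population's own column is the "auto" score, the full matrix
    feeds the linear-combination tuning.
    """
    X = dataset.genotypes[target_pop][partition]
    snp_pos = {s: j for j, s in enumerate(dataset.snp_id)}
    rows = np.array([snp_pos[s] for s in panel.snp_id])
    Xs = _standardize_columns(np.asarray(X, dtype=float)[:, rows])
    return Xs @ summary.beta_mean


def grid_fits(
    panel: HarmonizedPanel,
    blocks: LdBlockSet,
    phi_grid=(1e-6, 1e-4, 1e-2, 1.0, "auto"),
    seed: int = 0,
    n_iter: int | None = None,
    n_burnin: int | None = None,
    cons: float = 0.99,
) -> dict:
    """One chain per phi-grid entry (the validation-tuned workflows)."""
    return {
        phi: fit_joint(
            panel, blocks, phi=phi, seed=seed, n_iter=n_iter, n_burnin=n_burnin,
            cons=cons,
        )
        for phi in phi_grid
    }
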