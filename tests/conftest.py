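import numpy as np
import pytest

from crossprs.sumstats import HarmonizedPanel, LdBlock, LdBlockSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_panel(beta_hat, N, T=None, populations=None, chromosome=None):
    """Hand-built harmonized panel for sampler unit tests."""
    beta_hat = np.atleast_2d(np.asarray(beta_hat, dtype=float))
    S, K = beta_hat.shape
    if T is None:
        T = np.ones((S, K), dtype=np.uint8)
    T = np.asarray(T, dtype=np.uint8)
    beta = np.where(T == 1, beta_hat, np.nan)
    if populations is None:
        populations = [f"P{k+1}" for k in range(K)]
    if chromosome is None:
        chromosome = np.ones(S, dtype=int)
    return HarmonizedPanel(
        snp_id=np.asarray([f"rs{j+1}" for j in range(S)], dtype=object),
        chromosome=np.asarray(chromosome, dtype=int),
        populations=list(populations),
        T=T,
        beta_hat=beta,
        N=np.asarray(N, dtype=float),
        effect_allele=np.full(S, "A", dtype=object),
        other_allele=np.full(S, "G", dtype=object),
    )


def identity_blocks(panel, block_size=None):
    """One identity-LD block set covering each population's available SNPs."""
    blocks = {}
    for k, pop in enumerate(panel.populations):
        avail = np.flatnonzero(panel.T[:, k] == 1)
        size = block_size or len(avail)
        pop_blocks = []
        for b, lo in enumerate(range(0, len(avail), size)):
            idx = avail[lo:lo + size]
            pop_blocks.append(LdBlock(pop, b, idx, np.eye(len(idx))))
        blocks[pop] = pop_blocks
    return LdBlockSet(blocks=blocks)
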