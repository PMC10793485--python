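"""Joint Bayesian sampler for multi-population SNP effects.

The model couples the K populations' standardized SNP effects through a
correlated Gaussian prior

    beta_j ~ N(0, Psi_j * M Sigma M),      M = diag(1/sqrt(N_k)),

where Sigma = diag(sigma_k) * R * diag(sigma_k) combines the residual
variances with a per-chromosome correlation matrix R whose off-diagonal
entries rho_{k1k2} are the cross-population genetic correlations.  The local
scales Psi_j carry a gamma-gamma continuous shrinkage prior
Psi_j ~ G(a, delta_j), delta_j ~ G(b, phi), with the global scale phi either
fixed (grid value) or given a half-Cauchy prior on sqrt(phi) ("auto").
SNPs missing from some populations truncate the prior to the populations
that carry them, encoded by the panel's missingness matrix T.

Posterior computation is blocked Gibbs: multivariate-normal effect updates
within LD blocks, conjugate inverse-gamma residual variances, giG local
scales, gamma rates, and a random-walk Metropolis step for each correlation
pair restricted to [0, cons].  With cons = 0 the correlations are pinned at
zero and the model reduces to independent per-population continuous
shrinkage (the independent-populations limit used as an ablation).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .errors import DomainError, NumericalError
from .gig import sample_gig
from .sumstats import HarmonizedPanel, LdBlock, LdBlockSet

logger = logging.getLogger(__name__)

PHI_GRID_DEFAULT = (1e-6, 1e-4, 1e-2, 1.0, "auto")

__all__ = [
    "ModelHyper",
    "McmcConfig",
    "ChainState",
    "PosteriorSummary",
    "sample_beta_block",
    "sample_sigma2",
    "rho_log_density",
    "mh_update_rho",
    "sample_psi",
    "sample_delta",
    "sample_phi",
    "run_chain",
    "PHI_GRID_DEFAULT",
]


@dataclass
class ModelHyper:
    """Shrinkage-prior hyperparameters.

    a, b are the gamma shapes of Psi_j ~ G(a, delta_j) and delta_j ~ G(b, phi).
    phi_mode "auto" places the half-Cauchy prior on sqrt(phi); "fixed" pins
    phi at phi_value (one of the grid values in tuning workflows).
    """

    a: float = 1.0
    b: float = 0.5
    phi_mode: str = "auto"
    phi_value: float | None = None
    phi_grid: tuple = PHI_GRID_DEFAULT
    psi_max: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise DomainError("gamma shapes a, b must be positive")
        if self.phi_mode not in ("auto", "fixed"):
            raise DomainError("phi_mode must be 'auto' or 'fixed'")
        if self.phi_mode == "fixed":
            if self.phi_value is None or self.phi_value <= 0:
                raise DomainError("fixed phi requires positive phi_value")


@dataclass
class McmcConfig:
    """Chain settings.  n_iter/n_burnin default to 1000*K and 500*K.

    cons bounds each correlation to [0, cons]; it is forced to 0 when phi is
    fixed at 1e-6 (strong-shrinkage limit, where free correlations do not
    mix well).  The update_* flags freeze individual parameter groups, which
    is used by diagnostics and reduction tests; all default to True.
    """

    n_iter: int | None = None
    n_burnin: int | None = None
    thin: int = 1
    seed: int = 0
    delta_r: float = 0.05
    cons: float = 0.99
    update_psi: bool = True
    update_delta: bool = True
    update_sigma2: bool = True
    update_rho: bool = True
    sigma2_max: float = 1e6

    def resolve(self, n_pops: int) -> "McmcConfig":
        out = self
        if out.n_iter is None:
            out = replace(out, n_iter=1000 * n_pops)
        if out.n_burnin is None:
            out = replace(out, n_burnin=500 * n_pops)
        if not out.n_burnin < out.n_iter:
            raise DomainError("n_burnin must be < n_iter")
        return out


@dataclass
class ChainState:
    """All sampled quantities at one MCMC iteration (standardized scale)."""

    beta: np.ndarray            # (S, K), exact 0 where T = 0
    psi: np.ndarray             # (S,)
    delta: np.ndarray           # (S,)
    phi: float
    sigma2: np.ndarray          # (K,)
    R: dict                     # chromosome -> (K, K) correlation matrix
    xi: float = 1.0             # half-Cauchy auxiliary for phi-auto

    def copy(self) -> "ChainState":
        return ChainState(
            beta=self.beta.copy(),
            psi=self.psi.copy(),
            delta=self.delta.copy(),
            phi=self.phi,
            sigma2=self.sigma2.copy(),
            R={c: r.copy() for c, r in self.R.items()},
            xi=self.xi,
        )


@dataclass
class PosteriorSummary:
    """Post-burn-in posterior means and per-chromosome correlation estimates."""

    beta_mean: np.ndarray
    rho_mean: dict
    sigma2_mean: np.ndarray
    phi_mean: float
    n_samples_used: int
    rho_samples: dict = field(default_factory=dict)
    acceptance: dict = field(default_factory=dict)

    def rho_interval(self, chrom, k1: int, k2: int, level: float = 0.95):
        """Equal-tailed credible interval for one correlation pair."""
        s = self.rho_samples[chrom][:, k1, k2]
        lo = (1.0 - level) / 2.0
        return float(np.quantile(s, lo)), float(np.quantile(s, 1.0 - lo))


def initial_state(panel: HarmonizedPanel, hyper: ModelHyper) -> ChainState:
    """Standard starting point: null effects, unit scales, identity R."""
    S, K = panel.T.shape
    phi0 = hyper.phi_value if hyper.phi_mode == "fixed" else 1.0
    return ChainState(
        beta=np.zeros((S, K)),
        psi=np.ones(S),
        delta=np.ones(S),
        phi=float(phi0),
        sigma2=np.ones(K),
        R={c: np.eye(K) for c in np.unique(panel.chromosome)},
    )


# ---------------------------------------------------------------------------
# missingness-group machinery
# ---------------------------------------------------------------------------

def _group_index(panel: HarmonizedPanel):
    """Group SNPs by (chromosome, availability pattern).

    Returns (group_id per SNP, list of (chromosome, boolean mask over K)).
    The prior covariance restricted to a pattern is identical for every SNP
    in the group, so its inverse is computed once per iteration per group.
    """
    keys = {}
    groups: list[tuple] = []
    gid = np.empty(panel.n_snps, dtype=int)
    for j in range(panel.n_snps):
        key = (panel.chromosome[j], panel.T[j].tobytes())
        if key not in keys:
            keys[key] = len(groups)
            groups.append((panel.chromosome[j], panel.T[j].astype(bool).copy()))
        gid[j] = keys[key]
    return gid, groups


def _sigma_inv_stack(state: ChainState, groups) -> np.ndarray:
    """Inverse of the correlation-scaled prior covariance per group.

    For each (chromosome, pattern) group the truncated Sigma = Ds R Ds is
    inverted and embedded into a K x K matrix (zeros outside the pattern).
    """
    K = len(state.sigma2)
    out = np.zeros((len(groups), K, K))
    sig = np.sqrt(state.sigma2)
    for g, (chrom, mask) in enumerate(groups):
        idx = np.flatnonzero(mask)
        sub = state.R[chrom][np.ix_(idx, idx)] * np.outer(sig[idx], sig[idx])
        try:
            inv = np.linalg.inv(sub)
        except np.linalg.LinAlgError as e:
            raise NumericalError(f"singular prior covariance for group {g}") from e
        out[np.ix_([g], idx, idx)] = inv
    return out


# ---------------------------------------------------------------------------
# conditional updates
# ---------------------------------------------------------------------------

def sample_beta_block(
    block: LdBlock,
    state: ChainState,
    panel: HarmonizedPanel,
    rng,
    sigma_inv_stack: np.ndarray | None = None,
    group_id: np.ndarray | None = None,
) -> np.ndarray:
    """Gibbs draw of one population's effects within one LD block.

    The full conditional is multivariate normal with precision

        P = (N_k / sigma_k^2) * (D + sigma_k^2 * diag(Sig~_kk^{t_j} / Psi_j))

    and linear term (N_k/sigma_k^2) beta_hat minus the cross-population
    coupling sqrt(N_k N_k') Sig~_{kk'}^{t_j} beta_j^{k'} / Psi_j, where
    Sig~^{t_j} is the inverse of Sigma truncated to SNP j's populations.
    Updates state.beta in place and returns the drawn vector.
    """
    if group_id is None or sigma_inv_stack is None:
        group_id, groups = _group_index(panel)
        sigma_inv_stack = _sigma_inv_stack(state, groups)
    k = panel.populations.index(block.population_label)
    idx = block.snp_indices
    Nk = panel.N[k]
    sig2 = state.sigma2[k]
    sqrtN = np.sqrt(panel.N)

    W = sigma_inv_stack[group_id[idx], k, :]          # (s_l, K) row of Sig~
    psi = state.psi[idx]
    diag_kk = W[:, k]
    scaled = state.beta[idx] * sqrtN[None, :]         # masked entries are 0
    cross = (W * scaled).sum(axis=1) - diag_kk * scaled[:, k]
    b = sqrtN[k] * cross / psi

    beta_hat = np.nan_to_num(panel.beta_hat[idx, k])
    P = (Nk / sig2) * (block.D + sig2 * np.diag(diag_kk / psi))
    eta = (Nk / sig2) * beta_hat - b
    try:
        c, low = cho_factor(P, lower=True)
    except np.linalg.LinAlgError as e:
        raise NumericalError(
            f"non-invertible posterior precision in block {block.block_index} "
            f"of {block.population_label}"
        ) from e
    mu = cho_solve((c, low), eta)
    z = rng.standard_normal(len(idx))
    draw = mu + solve_triangular(c, z, lower=True, trans="T")
    state.beta[idx, k] = draw
    return draw


def sample_sigma2(
    k: int,
    state: ChainState,
    panel: HarmonizedPanel,
    blocks: LdBlockSet,
    rng,
) -> float:
    """Conjugate inverse-gamma draw of population k's residual variance.

    Shape (N_k + S_k)/2; scale (N_k/2)(1 - 2 sum beta' beta_hat
    + sum beta'(D + Psi^{-1})beta), clamped below at a small positive floor.
    Updates state.sigma2 in place.
    """
    pop = panel.populations[k]
    Nk = panel.N[k]
    Sk = int(panel.T[:, k].sum())
    lin = 0.0
    quad = 0.0
    prior_quad = 0.0
    for bl in blocks.for_population(pop):
        idx = bl.snp_indices
        b = state.beta[idx, k]
        bh = np.nan_to_num(panel.beta_hat[idx, k])
        lin += float(b @ bh)
        quad += float(b @ bl.D @ b)
        prior_quad += float(np.sum(b * b / state.psi[idx]))
    braced = 1.0 - 2.0 * lin + quad + prior_quad
    # reference/GWAS LD mismatch can push the residual part negative; floor
    # at the (always positive) prior quadratic so sigma2 cannot collapse
    floor = max(prior_quad, 1e-8)
    if braced < floor:
        logger.debug("population %s: sigma2 scale floored (%.3e)", pop, braced)
        braced = floor
    shape = 0.5 * (Nk + Sk)
    scale = 0.5 * Nk * braced
    draw = scale / rng.gamma(shape)
    state.sigma2[k] = draw
    return float(draw)


def _rho_suffstats(state, panel, k1, k2, snp_mask=None):
    shared = (panel.T[:, k1] == 1) & (panel.T[:, k2] == 1)
    if snp_mask is not None:
        shared &= snp_mask
    j = np.flatnonzero(shared)
    if len(j) == 0:
        return 0, 0.0, 0.0, 0.0
    b1 = state.beta[j, k1]
    b2 = state.beta[j, k2]
    invpsi = 1.0 / state.psi[j]
    n1, n2 = panel.N[k1], panel.N[k2]
    s1, s2 = np.sqrt(state.sigma2[k1]), np.sqrt(state.sigma2[k2])
    s11 = float(np.sum(invpsi * n1 * b1 * b1) / (s1 * s1))
    s22 = float(np.sum(invpsi * n2 * b2 * b2) / (s2 * s2))
    s12 = float(np.sum(invpsi * np.sqrt(n1 * n2) * b1 * b2) / (s1 * s2))
    return len(j), s11, s12, s22


def rho_log_density(
    rho: float,
    pair: tuple[int, int],
    state: ChainState,
    panel: HarmonizedPanel,
    snp_mask: np.ndarray | None = None,
) -> float:
    """Log full conditional of one correlation pair, up to a constant.

    The bivariate-normal prior of the shared SNPs' effects, viewed as a
    function of rho:

        -(S12/2) log(1 - rho^2)
        - [s11 - 2 rho s12 + s22] / (2 (1 - rho^2))

    with s11, s12, s22 the Psi- and N-weighted (co)moments of the two
    populations' current effects over SNPs carried by both.  Only SNPs with
    T=1 in both populations (optionally restricted by snp_mask, e.g. to one
    chromosome) contribute.
    """
    if not (0.0 <= rho < 1.0):
        raise DomainError("rho must lie in [0, 1)")
    S12, s11, s12, s22 = _rho_suffstats(state, panel, *pair, snp_mask)
    if S12 == 0:
        return 0.0
    om = 1.0 - rho * rho
    return -0.5 * S12 * np.log(om) - (s11 - 2.0 * rho * s12 + s22) / (2.0 * om)


def _r_is_pd(R: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(R)
        return True
    except np.linalg.LinAlgError:
        return False


def mh_update_rho(
    pair: tuple[int, int],
    state: ChainState,
    config: McmcConfig,
    panel: HarmonizedPanel,
    rng,
    chrom=None,
) -> bool:
    """Random-walk Metropolis step for one correlation pair.

    Proposes rho* ~ Uniform(rho - delta_r, rho + delta_r); proposals outside
    [0, cons] (or making R non-positive-definite for K >= 3) are rejected
    outright.  On acceptance the R entry (for the given chromosome) is
    refreshed.  Returns True on acceptance.
    """
    k1, k2 = pair
    if chrom is None:
        chrom = next(iter(state.R))
    R = state.R[chrom]
    rho = R[k1, k2]
    prop = rho + config.delta_r * (2.0 * rng.random() - 1.0)
    if not (0.0 <= prop <= config.cons):
        return False
    snp_mask = panel.chromosome == chrom if len(state.R) > 1 else None
    if len(state.sigma2) >= 3:
        cand = R.copy()
        cand[k1, k2] = cand[k2, k1] = prop
        if not _r_is_pd(cand):
            return False
    log_ratio = rho_log_density(prop, pair, state, panel, snp_mask) - rho_log_density(
        rho, pair, state, panel, snp_mask
    )
    if np.log(rng.random() + 1e-300) <= log_ratio:
        R[k1, k2] = R[k2, k1] = prop
        return True
    return False


def _psi_chi_all(state, panel, sigma_inv_stack, group_id) -> np.ndarray:
    """chi_j = (sqrt(N) beta_j)' Sig~^{t_j} (sqrt(N) beta_j) for every SNP."""
    B = state.beta * np.sqrt(panel.N)[None, :]
    Sig = sigma_inv_stack[group_id]
    return np.einsum("jk,jkl,jl->j", B, Sig, B)


def sample_psi(
    j: int,
    state: ChainState,
    panel: HarmonizedPanel,
    hyper: ModelHyper,
    rng,
    sigma_inv_stack: np.ndarray | None = None,
    group_id: np.ndarray | None = None,
) -> float:
    """giG draw of SNP j's local shrinkage scale.

    Psi_j ~ giG(a - K_j/2, 2 delta_j, beta_j' Sig~^{t_j} beta_j) with K_j the
    number of populations carrying SNP j; a positivity floor of 1e-12 guards
    against underflow, and draws are capped at hyper.psi_max (the local scale
    is bounded, the global scale phi carries overall magnitude — the standard
    stabilization in this sampler family).  Updates state.psi in place.
    """
    if group_id is None or sigma_inv_stack is None:
        group_id, groups = _group_index(panel)
        sigma_inv_stack = _sigma_inv_stack(state, groups)
    Kj = int(panel.T[j].sum())
    btil = state.beta[j] * np.sqrt(panel.N)
    chi = float(btil @ sigma_inv_stack[group_id[j]] @ btil)
    lam = hyper.a - 0.5 * Kj
    if lam <= 0:
        chi = max(chi, 1e-12)
    draw = min(max(sample_gig(lam, chi, 2.0 * state.delta[j], rng), 1e-12), hyper.psi_max)
    state.psi[j] = draw
    return draw


def _sample_psi_all(state, panel, hyper, rng, sigma_inv_stack, group_id) -> np.ndarray:
    chi = _psi_chi_all(state, panel, sigma_inv_stack, group_id)
    lam = hyper.a - 0.5 * panel.T.sum(axis=1)
    chi = np.where(lam <= 0, np.maximum(chi, 1e-12), chi)
    draws = sample_gig(lam, chi, 2.0 * state.delta, rng)
    state.psi[:] = np.clip(draws, 1e-12, hyper.psi_max)
    return state.psi


def sample_delta(j: int, state: ChainState, hyper: ModelHyper, rng) -> float:
    """Conjugate gamma draw: delta_j ~ G(a + b, Psi_j + phi)."""
    draw = rng.gamma(hyper.a + hyper.b, 1.0 / (state.psi[j] + state.phi))
    state.delta[j] = draw
    return float(draw)


def _sample_delta_all(state, hyper, rng) -> np.ndarray:
    state.delta[:] = rng.gamma(hyper.a + hyper.b, 1.0 / (state.psi + state.phi))
    return state.delta


def sample_phi(state: ChainState, hyper: ModelHyper, S: int, rng) -> float:
    """Global-scale update under the half-Cauchy prior on sqrt(phi).

    Uses the inverse-gamma auxiliary representation: with xi | phi ~
    iG(1, 1 + 1/phi), the conditional of phi given the delta's is
    giG(S*b - 1/2, 2 sum(delta), 2/xi).  Returns phi_value unchanged when
    phi_mode is "fixed".
    """
    if hyper.phi_mode == "fixed":
        state.phi = float(hyper.phi_value)
        return state.phi
    state.xi = float((1.0 + 1.0 / state.phi) / rng.gamma(1.0))
    lam = S * hyper.b - 0.5
    draw = sample_gig(lam, 2.0 / state.xi, 2.0 * float(np.sum(state.delta)), rng)
    state.phi = float(max(draw, 1e-300))
    return state.phi


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

def _stream(seed: int, name: str):
    """Deterministic child generator keyed by a stable string hash.

    Population-keyed streams make a joint run over disjoint SNP sets match a
    restricted single-population run draw-for-draw under the same seed.
    """
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def run_chain(
    panel: HarmonizedPanel,
    blocks: LdBlockSet,
    hyper: ModelHyper,
    config: McmcConfig,
) -> PosteriorSummary:
    """Run the full Gibbs/Metropolis chain and accumulate posterior means.

    Per iteration: effect blocks per population (input order), residual
    variances, correlation pairs per chromosome, local scales, rates, and the
    global scale when phi_mode is "auto".  Deterministic given config.seed.
    """
    S, K = panel.T.shape
    config = config.resolve(K)
    if hyper.phi_mode == "fixed" and hyper.phi_value <= 1e-6:
        config = replace(config, cons=0.0)

    state = initial_state(panel, hyper)
    group_id, groups = _group_index(panel)
    chroms = list(np.unique(panel.chromosome))
    pairs = [(i, j) for i in range(K - 1) for j in range(i + 1, K)]
    rng_beta = {p: _stream(config.seed, f"beta:{p}") for p in panel.populations}
    rng_sigma = {p: _stream(config.seed, f"sigma2:{p}") for p in panel.populations}
    rng_rho = _stream(config.seed, "rho")
    rng_psi = _stream(config.seed, "psi")
    rng_delta = _stream(config.seed, "delta")
    rng_phi = _stream(config.seed, "phi")

    beta_sum = np.zeros((S, K))
    sigma2_sum = np.zeros(K)
    phi_sum = 0.0
    rho_kept = {c: [] for c in chroms}
    n_used = 0
    accept = {(c, p): 0 for c in chroms for p in pairs}
    attempts = 0

    for it in range(config.n_iter):
        stack = _sigma_inv_stack(state, groups)
        for pop in panel.populations:
            rng_k = rng_beta[pop]
            for bl in blocks.for_population(pop):
                sample_beta_block(bl, state, panel, rng_k, stack, group_id)
        if config.update_sigma2:
            for k, pop in enumerate(panel.populations):
                sample_sigma2(k, state, panel, blocks, rng_sigma[pop])
                if not (1e-12 < state.sigma2[k] < config.sigma2_max):
                    raise NumericalError(
                        f"sigma2 divergence in population {pop} at iteration {it}: "
                        f"{state.sigma2[k]:.3e}"
                    )
        if config.update_rho and config.cons > 0.0 and K > 1:
            attempts += 1
            for c in chroms:
                for pair in pairs:
                    if mh_update_rho(pair, state, config, panel, rng_rho, chrom=c):
                        accept[(c, pair)] += 1
        if config.update_psi:
            stack = _sigma_inv_stack(state, groups)
            _sample_psi_all(state, panel, hyper, rng_psi, stack, group_id)
        if config.update_delta:
            _sample_delta_all(state, hyper, rng_delta)
        if hyper.phi_mode == "auto":
            sample_phi(state, hyper, S, rng_phi)
        else:
            state.phi = float(hyper.phi_value)

        if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
            n_used += 1
            beta_sum += state.beta
            sigma2_sum += state.sigma2
            phi_sum += state.phi
            for c in chroms:
                rho_kept[c].append(state.R[c].copy())

    acc_rate = {
        key: (n / attempts if attempts else 0.0) for key, n in accept.items()
    }
    for key, rate in acc_rate.items():
        logger.info("MH acceptance chrom=%s pair=%s: %.3f", key[0], key[1], rate)
    rho_samples = {c: np.array(v) for c, v in rho_kept.items()}
    return PosteriorSummary(
        beta_mean=beta_sum / n_used,
        rho_mean={c: rho_samples[c].mean(axis=0) for c in chroms},
        sigma2_mean=sigma2_sum / n_used,
        phi_mean=phi_sum / n_used,
        n_samples_used=n_used,
        rho_samples=rho_samples,
        acceptance=acc_rate,
    )
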