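"""Two-isotope Bayesian stable-isotope mixing model (SIMM) with residual error.

Model
-----
A consumer's tissue signature is a proportion-weighted mixture of diet
sources, shifted by a trophic discrimination factor (TDF).  For consumer
``i`` and isotope ``j`` (j = d13C, d15N):

    X_ij ~ Normal( sum_k p_k (mu_jk + Delta_j),
                   sum_k p_k^2 (sigma_jk^2 + tau_j^2) + sigma_res_j^2 )

where ``p`` is the K-vector of diet proportions on the simplex,
``(mu_jk, sigma_jk)`` are the source moments, ``(Delta_j, tau_j)`` the TDF
mean and SD, and ``sigma_res_j`` a residual SD absorbing individual
variation not captured by source mixing.  This is the marginalised
residual-error SIMM: per-consumer latent source draws are integrated out,
isotopes are conditionally independent, and no source covariance is
modelled.

Priors are an uninformative Dirichlet(1, ..., 1) on ``p`` and Uniform(0,
``residual_sd_max``) on each residual SD.

Inference is adaptive random-walk Metropolis on unconstrained
coordinates: an additive log-ratio (ALR) transform of ``p`` with the last
source as reference (Jacobian included, so the prior on ``p`` is exactly
Dirichlet) and a scaled-logit transform of each residual SD.  The
proposal scale adapts only during burn-in, targeting acceptance in
0.2-0.5; retained draws are thinned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, gammaln

from .isotope_core import SourceDistribution

logger = logging.getLogger("nichemix")

__all__ = [
    "DiscriminationFactor",
    "MixingProblem",
    "ChainConfig",
    "PosteriorDraw",
    "Chain",
    "DietEstimate",
    "adjust_sources",
    "log_posterior",
    "sample_posterior",
    "gelman_rubin",
    "split_rhat",
    "effective_sample_size",
    "summarize_posterior",
    "geometric_point_estimate",
]

#: Rodent diet-to-hair trophic discrimination defaults (permil).
DEFAULT_TDF_C = 3.4
DEFAULT_TDF_N = 2.4


@dataclass(frozen=True)
class DiscriminationFactor:
    """Diet-to-tissue isotopic offset, mean and SD per isotope (permil)."""

    delta: tuple[float, float] = (DEFAULT_TDF_C, DEFAULT_TDF_N)
    sd: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd):
            raise ValueError(f"TDF sd must be >= 0, got {self.sd}")


@dataclass
class MixingProblem:
    """Everything the sampler needs: consumers, sources, TDF, priors."""

    consumers: np.ndarray  # (n, 2) of (d13c, d15n)
    sources: Sequence[SourceDistribution]
    tdf: DiscriminationFactor = field(default_factory=DiscriminationFactor)
    prior_alpha: np.ndarray | None = None
    residual_sd_max: float = 20.0

    def __post_init__(self) -> None:
        self.consumers = np.atleast_2d(np.asarray(self.consumers, dtype=float))
        if self.consumers.shape[0] < 1 or self.consumers.shape[1] != 2:
            raise ValueError("consumers must be an (n, 2) matrix with n >= 1")
        if len(self.sources) < 1:
            raise ValueError("need at least one source")
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError(f"source names must be unique, got {names}")
        if self.prior_alpha is None:
            self.prior_alpha = np.ones(len(self.sources))
        self.prior_alpha = np.asarray(self.prior_alpha, dtype=float)
        if self.prior_alpha.shape != (len(self.sources),) or np.any(self.prior_alpha <= 0):
            raise ValueError("prior_alpha must be a positive K-vector")
        if self.residual_sd_max <= 0:
            raise ValueError("residual_sd_max must be > 0")

    @property
    def n_consumers(self) -> int:
        return self.consumers.shape[0]

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings (defaults: 3 chains, 10k burn-in, 40k draws, thin 10)."""

    chains: int = 3
    burn_in: int = 10_000
    iterations: int = 40_000
    thin: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in < 0 or self.iterations < 1:
            raise ValueError("burn_in must be >= 0 and iterations >= 1")


@dataclass(frozen=True)
class PosteriorDraw:
    """One retained MCMC draw: diet proportions and residual SDs."""

    p: np.ndarray
    sigma_res: np.ndarray


@dataclass
class Chain:
    """Retained draws of one MCMC chain, stored column-wise."""

    p: np.ndarray  # (m, K)
    sigma_res: np.ndarray  # (m, 2)
    acceptance: float
    proposal_scale: float

    def __len__(self) -> int:
        return self.p.shape[0]

    def __iter__(self):
        for i in range(len(self)):
            yield PosteriorDraw(self.p[i], self.sigma_res[i])


@dataclass
class DietEstimate:
    """Posterior diet summary: per-source mean and 95% credible interval."""

    source_names: list[str]
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    sigma_res_mean: np.ndarray
    rhat: dict[str, float]
    ess: dict[str, float]
    acceptance: list[float]
    converged: bool

    def to_rows(self, round_to: int = 2) -> list[dict]:
        """Report-layer rows, rounded to ``round_to`` decimals."""
        return [
            {
                "source": nm,
                "mean": round(float(m), round_to),
                "lo95": round(float(lo), round_to),
                "hi95": round(float(hi), round_to),
            }
            for nm, m, lo, hi in zip(self.source_names, self.mean, self.lo95, self.hi95)
        ]


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def adjust_sources(
    sources: Sequence[SourceDistribution], tdf: DiscriminationFactor
) -> tuple[np.ndarray, np.ndarray]:
    """Shift source moments by the TDF.

    Returns ``(means, variances)``, each (K, 2): per isotope j the adjusted
    mean is ``mu_jk + Delta_j`` and the adjusted variance is
    ``sigma_jk^2 + tau_j^2`` (TDF uncertainty adds on the variance scale).
    """
    mu = np.array([s.mean_array for s in sources], dtype=float)
    var = np.array([s.sd_array**2 for s in sources], dtype=float)
    delta = np.asarray(tdf.delta, dtype=float)
    tau2 = np.asarray(tdf.sd, dtype=float) ** 2
    return mu + delta, var + tau2


_LOG_2PI = math.log(2.0 * math.pi)


def _suff_stats(consumers: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    """(n, sum_i x_ij, sum_i x_ij^2) per isotope; consumers are iid given
    the parameters, so these are sufficient for the Gaussian likelihood."""
    n = consumers.shape[0]
    return n, consumers.sum(axis=0), (consumers**2).sum(axis=0)


def _loglik_from_stats(
    p: np.ndarray,
    sigma_res: np.ndarray,
    adj_mu: np.ndarray,
    adj_var: np.ndarray,
    n: int,
    sx: np.ndarray,
    sxx: np.ndarray,
) -> float:
    """Gaussian log-likelihood of all consumers for mixture weights p."""
    m = p @ adj_mu  # (2,) mixture mean per isotope
    v = (p**2) @ adj_var + sigma_res**2  # (2,) mixture variance per isotope
    # sum_i (x_ij - m_j)^2 = sxx_j - 2 m_j sx_j + n m_j^2
    ss = sxx - 2.0 * m * sx + n * m * m
    return float(np.sum(-0.5 * n * (_LOG_2PI + np.log(v)) - ss / (2.0 * v)))


def _dirichlet_logpdf(p: np.ndarray, alpha: np.ndarray) -> float:
    lognorm = float(gammaln(alpha.sum()) - gammaln(alpha).sum())
    return lognorm + float(np.sum((alpha - 1.0) * np.log(p)))


def log_posterior(draw: PosteriorDraw, problem: MixingProblem, prior_only: bool = False) -> float:
    """Unnormalised log posterior density of one draw.

    Returns ``-inf`` (never raises) for draws outside the support: any
    negative proportion, proportions not summing to 1 within 1e-12, or a
    residual SD outside ``(0, residual_sd_max)``.
    """
    p = np.asarray(draw.p, dtype=float)
    sig = np.asarray(draw.sigma_res, dtype=float)
    if p.shape != (problem.n_sources,) or sig.shape != (2,):
        raise ValueError("draw dimensions do not match problem")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
        return -math.inf
    if np.any(sig <= 0) or np.any(sig >= problem.residual_sd_max):
        return -math.inf
    if np.any(p == 0) and np.any(problem.prior_alpha < 1):
        return -math.inf
    adj_mu, adj_var = adjust_sources(problem.sources, problem.tdf)
    # boundary p=0 with alpha>=1: log p term contributes 0 * log 0 -> use xlogy-safe path
    with np.errstate(divide="ignore", invalid="ignore"):
        logp_terms = np.where(p > 0, (problem.prior_alpha - 1.0) * np.log(np.maximum(p, 1e-300)), 0.0)
    lp = float(gammaln(problem.prior_alpha.sum()) - gammaln(problem.prior_alpha).sum() + logp_terms.sum())
    lp -= 2.0 * math.log(problem.residual_sd_max)  # flat prior on each sigma
    if not prior_only:
        n, sx, sxx = _suff_stats(problem.consumers)
        lp += _loglik_from_stats(p, sig, adj_mu, adj_var, n, sx, sxx)
    return lp


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _theta_to_params(theta: np.ndarray, K: int, sd_max: float) -> tuple[np.ndarray, np.ndarray]:
    """Unconstrained coordinates -> (p on simplex, sigma_res in (0, max)).

    ALR with the last source as reference: p_k proportional to exp(z_k),
    z_K = 0.  Residual SDs via sigma = sd_max * expit(t).
    """
    z = np.concatenate([theta[: K - 1], [0.0]])
    z -= z.max()
    ez = np.exp(z)
    p = ez / ez.sum()
    sigma = sd_max * expit(theta[K - 1 :])
    return p, sigma


def _make_logpost_theta(problem: MixingProblem, prior_only: bool = False):
    """Fast closure: log posterior in unconstrained coordinates, with the
    ALR and logit Jacobians so the priors on (p, sigma) are exact."""
    K = problem.n_sources
    alpha = problem.prior_alpha
    sd_max = problem.residual_sd_max
    adj_mu, adj_var = adjust_sources(problem.sources, problem.tdf)
    n, sx, sxx = _suff_stats(problem.consumers)

    def logpost(theta: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        p, sigma = _theta_to_params(theta, K, sd_max)
        if np.any(p <= 0.0) or np.any(sigma <= 0.0) or np.any(sigma >= sd_max):
            return -math.inf, p, sigma
        logp = np.log(p)
        # Dirichlet(alpha) on p + ALR Jacobian sum(log p_k)  =>  sum(alpha_k log p_k)
        lp = float(alpha @ logp)
        # flat prior on sigma + logit Jacobian: log(sigma (1 - sigma/sd_max))
        lp += float(np.sum(np.log(sigma) + np.log1p(-sigma / sd_max)))
        if not prior_only:
            m = p @ adj_mu
            v = (p * p) @ adj_var + sigma * sigma
            ss = sxx - 2.0 * m * sx + n * m * m
            lp += float(np.sum(-0.5 * n * (_LOG_2PI + np.log(v)) - ss / (2.0 * v)))
        if not math.isfinite(lp):
            return -math.inf, p, sigma
        return lp, p, sigma

    return logpost


def _initial_theta(problem: MixingProblem, rng: np.random.Generator) -> np.ndarray:
    """Initialise at the geometric point estimate projected inside the
    simplex (floor 0.01), falling back to the uniform composition."""
    K = problem.n_sources
    p0 = np.full(K, 1.0 / K)
    if 2 <= K <= 3:
        try:
            p_geo, _ = geometric_point_estimate(problem)
            p0 = np.maximum(p_geo, 0.01)
            p0 /= p0.sum()
        except np.linalg.LinAlgError:
            pass
    z = np.log(p0[:-1] / p0[-1]) if K > 1 else np.empty(0)
    resid_sd = max(problem.consumers.std(axis=0).mean(), 0.1)
    frac = min(resid_sd / problem.residual_sd_max, 0.9)
    t = np.full(2, math.log(frac / (1.0 - frac)))
    theta = np.concatenate([z, t])
    return theta + 0.01 * rng.standard_normal(theta.size)


def _run_chain(
    problem: MixingProblem, config: ChainConfig, rng: np.random.Generator, prior_only: bool
) -> Chain:
    K = problem.n_sources
    dim = (K - 1) + 2
    logpost = _make_logpost_theta(problem, prior_only=prior_only)

    theta = _initial_theta(problem, rng)
    lp, p, sigma = logpost(theta)
    tries = 0
    while not math.isfinite(lp):
        tries += 1
        if tries > 10:
            raise RuntimeError("could not find a finite-posterior initial point in 10 tries")
        theta = _initial_theta(problem, rng) + 0.5 * rng.standard_normal(dim)
        lp, p, sigma = logpost(theta)

    scale = 2.38 / math.sqrt(dim)
    batch = 50
    acc_batch = 0
    n_batches = 0

    n_keep = config.iterations // config.thin
    out_p = np.empty((n_keep, K))
    out_sigma = np.empty((n_keep, 2))
    kept = 0
    accepted_post = 0
    total = config.burn_in + config.iterations

    normals = None  # drawn in blocks to cut RNG call overhead
    unifs = None
    block = 4096
    bi = block

    for it in range(total):
        if bi == block:
            normals = rng.standard_normal((block, dim))
            unifs = rng.random(block)
            bi = 0
        prop = theta + scale * normals[bi]
        lp_prop, p_prop, sig_prop = logpost(prop)
        if lp_prop - lp > math.log(unifs[bi] + 1e-300):
            theta, lp, p, sigma = prop, lp_prop, p_prop, sig_prop
            accepted = True
        else:
            accepted = False
        bi += 1

        in_burn = it < config.burn_in
        if in_burn:
            acc_batch += accepted
            if (it + 1) % batch == 0:
                n_batches += 1
                rate = acc_batch / batch
                delta = min(0.25, 1.0 / math.sqrt(n_batches))
                if rate > 0.35:
                    scale *= math.exp(delta)
                elif rate < 0.25:
                    scale *= math.exp(-delta)
                acc_batch = 0
        else:
            accepted_post += accepted
            j = it - config.burn_in
            if (j + 1) % config.thin == 0:
                out_p[kept] = p
                out_sigma[kept] = sigma
                kept += 1

    acc_rate = accepted_post / config.iterations
    if acc_rate < 0.02:
        logger.warning("MCMC chain acceptance rate %.4f < 0.02 after adaptation", acc_rate)
    return Chain(p=out_p[:kept], sigma_res=out_sigma[:kept], acceptance=acc_rate, proposal_scale=scale)


def sample_posterior(
    problem: MixingProblem, config: ChainConfig | None = None, prior_only: bool = False
) -> list[Chain]:
    """Run multi-chain adaptive random-walk Metropolis on a mixing problem.

    A single user seed deterministically spawns independent per-chain RNG
    streams.  With ``prior_only=True`` the likelihood is switched off and
    the chains target the prior (useful for prior-recovery checks).
    """
    if config is None:
        config = ChainConfig()
    ss = np.random.SeedSequence(config.seed)
    chains = []
    for child in ss.spawn(config.chains):
        chains.append(_run_chain(problem, config, np.random.default_rng(child), prior_only))
    return chains


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    ``x`` is (n_chains, n_draws); each chain is split in half, then the
    classic between/within variance ratio is computed on the 2m half
    chains.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    n = x.shape[1] - (x.shape[1] % 2)
    if n < 4:
        raise ValueError("chains too short to split")
    halves = x[:, :n].reshape(x.shape[0] * 2, n // 2)
    m, nn = halves.shape
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    W = chain_vars.mean()
    B = nn * chain_means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else math.inf
    var_plus = (nn - 1) / nn * W + B / nn
    return math.sqrt(var_plus / W)


def _param_matrix(chains: Sequence[Chain]) -> dict[str, np.ndarray]:
    """Stack chains into per-parameter (n_chains, n_draws) arrays."""
    lengths = {len(c) for c in chains}
    if len(lengths) != 1:
        raise ValueError(f"chains have unequal retained lengths: {sorted(lengths)}")
    K = chains[0].p.shape[1]
    out = {}
    for k in range(K):
        out[f"p[{k}]"] = np.stack([c.p[:, k] for c in chains])
    for j, nm in enumerate(("sigma_res[c]", "sigma_res[n]")):
        out[nm] = np.stack([c.sigma_res[:, j] for c in chains])
    return out


def gelman_rubin(chains: Sequence[Chain]) -> dict[str, float]:
    """Split-R-hat per parameter across chains of retained draws."""
    if len(chains) < 2:
        raise ValueError("need >= 2 chains")
    if any(len(c) < 50 for c in chains):
        raise ValueError("need >= 50 retained draws per chain for R-hat")
    return {name: split_rhat(x) for name, x in _param_matrix(chains).items()}


def effective_sample_size(x: np.ndarray) -> float:
    """Multi-chain effective sample size for one parameter.

    Combines within-chain FFT autocorrelations with Geyer's initial
    monotone positive-pair truncation: ESS = m*n / (1 + 2 sum rho_t).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    m, n = x.shape
    if n < 4:
        return float(m * n)
    # within-chain autocovariances via FFT
    xc = x - x.mean(axis=1, keepdims=True)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, :n].real / n
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B_over_n
    if var_plus == 0.0:
        return float(m * n)
    rho = 1.0 - (W - acov.mean(axis=0)) / var_plus
    # Geyer: sum consecutive pairs while positive and non-increasing
    tau = 1.0
    prev_pair = math.inf
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0.0:
            break
        pair = min(pair, prev_pair)
        tau += 2.0 * pair
        prev_pair = pair
        t += 2
    return float(m * n / tau)


RHAT_THRESHOLD = 1.1


def summarize_posterior(chains: Sequence[Chain], problem: MixingProblem) -> DietEstimate:
    """Pool retained draws into per-source means and equal-tailed 95% CrIs.

    Diagnostics (split-R-hat, ESS, acceptance) ride along; an R-hat above
    1.1 on any parameter triggers a prominent non-convergence warning but
    the summary is still produced.
    """
    pooled_p = np.concatenate([c.p for c in chains])
    pooled_sig = np.concatenate([c.sigma_res for c in chains])
    if pooled_p.shape[0] < 1000:
        raise ValueError(f"need >= 1000 pooled retained draws, got {pooled_p.shape[0]}")
    rhat = gelman_rubin(chains)
    ess = {name: effective_sample_size(x) for name, x in _param_matrix(chains).items()}
    converged = all(r < RHAT_THRESHOLD for r in rhat.values())
    if not converged:
        bad = {k: round(v, 3) for k, v in rhat.items() if v >= RHAT_THRESHOLD}
        logger.warning("NON-CONVERGENCE: R-hat >= %.2f for %s", RHAT_THRESHOLD, bad)
    return DietEstimate(
        source_names=problem.source_names,
        mean=pooled_p.mean(axis=0),
        lo95=np.percentile(pooled_p, 2.5, axis=0),
        hi95=np.percentile(pooled_p, 97.5, axis=0),
        sigma_res_mean=pooled_sig.mean(axis=0),
        rhat=rhat,
        ess=ess,
        acceptance=[c.acceptance for c in chains],
        converged=converged,
    )


# ---------------------------------------------------------------------------
# geometric (mixing-polygon) point estimate
# ---------------------------------------------------------------------------

def geometric_point_estimate(problem: MixingProblem) -> tuple[np.ndarray, bool]:
    """Deterministic mass-balance solve for the mean consumer.

    With two isotopes plus the sum-to-one constraint, up to three sources
    are exactly identified: solve ``sum_k p_k mu'_jk = xbar_j`` (j = C, N)
    and ``sum_k p_k = 1`` for p.  Returns ``(p, feasible)`` where
    ``feasible`` is False when any component falls outside [0, 1] — the
    consumer mean lies outside the adjusted mixing polygon.

    Raises for K > 3 (under-determined) and for geometrically degenerate
    (collinear) source configurations.
    """
    K = problem.n_sources
    if K > 3:
        raise ValueError("geometric point estimate requires K <= 3 (2 isotopes + mass balance)")
    adj_mu, _ = adjust_sources(problem.sources, problem.tdf)
    target = problem.consumers.mean(axis=0)
    if K == 1:
        return np.array([1.0]), True
    A = np.vstack([adj_mu.T, np.ones(K)])  # (3, K)
    b = np.concatenate([target, [1.0]])
    if K == 3:
        if abs(np.linalg.det(A)) < 1e-10:
            raise np.linalg.LinAlgError(
                "sources are collinear in isotope space; mixing polygon is degenerate"
            )
        p = np.linalg.solve(A, b)
    else:  # K == 2: overdetermined; least squares under the constraint
        p, *_ = np.linalg.lstsq(A, b, rcond=None)
    feasible = bool(np.all(p >= -1e-9) and np.all(p <= 1.0 + 1e-9))
    return p, feasible
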