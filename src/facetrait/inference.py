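"""MCMC fitting, convergence diagnostics, and HDI-based significance.

The sampler is an adaptive Hamiltonian Monte Carlo: leapfrog integration
with a jittered number of steps, dual-averaging step-size adaptation toward
a target acceptance rate, and a diagonal mass matrix estimated from warmup
draws. The default schedule is four chains of 2000 iterations each with the
first 1000 discarded as warmup, so 4 x 1000 = 4000 draws are retained.

Convergence is assessed with the split potential-scale-reduction factor
(split R-hat; values below 1.1 are treated as converged), and a coefficient
is called significant when its 95% highest-density interval excludes zero
(zero on the boundary counts as included).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import _PackedPosterior

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class MCMCSchedule:
    """Sampling schedule: ``iterations`` counts warmup + retained per chain."""

    chains: int = 4
    warmup: int = 1000
    iterations: int = 2000

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 0 or self.iterations <= self.warmup:
            raise ValueError("need chains >= 1 and iterations > warmup >= 0")

    @property
    def retained(self) -> int:
        return self.iterations - self.warmup


@dataclass(frozen=True)
class HDIInterval:
    """Shortest interval holding ``mass`` of the posterior draws."""

    lower: float
    upper: float
    mass: float = 0.95

    def excludes_zero(self) -> bool:
        """Strict exclusion: 0 on the boundary counts as included."""
        return self.lower > 0.0 or self.upper < 0.0


@dataclass
class PosteriorDraws:
    """Named posterior sample arrays, each shaped (chain, draw, *block).

    ``dims`` optionally carries axis labels per block (e.g. expressions x
    areas for a fixed-effect matrix) used to build human-readable
    coefficient names like ``beta[happiness,upper]``.
    """

    draws: dict[str, np.ndarray]
    dims: dict[str, tuple[tuple[str, ...], ...]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.n_draws

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (chain*draw, *block)."""
        arr = self.draws[name]
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_views(self, names: list[str] | None = None):
        """Yield (label, (chain, draw) array) for every scalar coefficient."""
        for name in names or self.draws:
            arr = self.draws[name]
            block_shape = arr.shape[2:]
            if not block_shape:
                yield name, arr
                continue
            labels = self.dims.get(name)
            for idx in np.ndindex(*block_shape):
                if labels:
                    tag = ",".join(str(labels[ax][i]) for ax, i in enumerate(idx))
                else:
                    tag = ",".join(str(i) for i in idx)
                yield f"{name}[{tag}]", arr[(slice(None), slice(None), *idx)]

    def rhat_table(self, names: list[str] | None = None) -> pd.Series:
        return pd.Series({lab: split_rhat(a) for lab, a in self.scalar_views(names)})

    def max_rhat(self, names: list[str] | None = None) -> float:
        return float(self.rhat_table(names).max())


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def split_rhat(samples: np.ndarray) -> float:
    """Split potential-scale-reduction factor of a (chain, draw) array.

    Each chain is split in half (the middle draw is dropped when the count
    is odd); R-hat compares between- to within-half variance.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be a (chain, draw) array")
    c, n = samples.shape
    if c < 2:
        raise ValueError("split R-hat requires at least 2 chains")
    if n < 4:
        raise ValueError("split R-hat requires at least 4 draws per chain")
    half = n // 2
    halves = np.concatenate([samples[:, :half], samples[:, n - half :]], axis=0)
    m, n_h = halves.shape
    within = halves.var(axis=1, ddof=1).mean()
    between = n_h * halves.mean(axis=1).var(ddof=1)
    if within == 0.0:
        return 1.0 if between == 0.0 else math.inf
    var_plus = (n_h - 1) / n_h * within + between / n_h
    return float(math.sqrt(var_plus / within))


def rhat(draws: PosteriorDraws, coefficient: str) -> float:
    """Split R-hat for one named coefficient (max over block elements)."""
    values = [a for lab, a in draws.scalar_views() if lab == coefficient]
    if not values:
        if coefficient in draws.draws:
            return draws.max_rhat([coefficient])
        raise KeyError(f"unknown coefficient {coefficient!r}")
    return split_rhat(values[0])


def hdi(samples: np.ndarray, mass: float = 0.95) -> HDIInterval:
    """Shortest contiguous interval containing ceil(mass*n) sorted draws.

    Ties are broken toward the lowest lower bound.
    """
    samples = np.sort(np.asarray(samples, dtype=float).ravel())
    n = samples.size
    if n < 2:
        raise ValueError("hdi requires at least 2 samples")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    m = min(n, int(math.ceil(mass * n)))
    widths = samples[m - 1 :] - samples[: n - m + 1]
    i = int(np.argmin(widths))  # first minimum -> lowest lower bound
    return HDIInterval(float(samples[i]), float(samples[i + m - 1]), mass)


def significance_table(
    draws: PosteriorDraws,
    block: str = "beta",
    condition: str | None = None,
    mass: float = 0.95,
    response_column: str = "Response",
    extra: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate fixed effects: posterior mean, HDI, and significance.

    One row per (response, predictor) element of the named block, ordered by
    response then predictor. Significant means the HDI strictly excludes 0.
    A warning (not an error) is emitted when any monitored coefficient has
    split R-hat above 1.1.
    """
    max_r = draws.max_rhat()
    if max_r > RHAT_THRESHOLD:
        warnings.warn(
            f"max split R-hat {max_r:.3f} exceeds {RHAT_THRESHOLD}; "
            "fit may not have converged",
            stacklevel=2,
        )
    arr = draws.draws[block]
    labels = draws.dims.get(block)
    if arr.ndim != 4:
        raise ValueError(f"block {block!r} must be a (chain, draw, K, P) array")
    _, _, K, P = arr.shape
    rows = []
    condition = condition or draws.meta.get("condition")
    for k in range(K):
        for p in range(P):
            samp = arr[:, :, k, p].ravel()
            interval = hdi(samp, mass)
            row = {
                "Expression": condition,
                response_column: labels[0][k] if labels else str(k),
                "Predictor": labels[1][p] if labels else str(p),
                "Mean": float(samp.mean()),
                "HDI_low": interval.lower,
                "HDI_high": interval.upper,
                "Significant": interval.excludes_zero(),
            }
            if extra:
                row = {**extra, **row}
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------


def _leapfrog(target, theta, rho, eps, m_inv, grad, n_steps):
    rho = rho + 0.5 * eps * grad
    for step in range(n_steps):
        theta = theta + eps * m_inv * rho
        logp, grad = target.logp_and_grad(theta)
        if not np.all(np.isfinite(grad)) or not np.isfinite(logp):
            return theta, rho, -math.inf, grad
        rho = rho + (eps if step < n_steps - 1 else 0.5 * eps) * grad
    return theta, rho, logp, grad


def _find_initial_step(target, theta, logp, grad, m_inv, rng):
    eps = 0.1
    rho = rng.standard_normal(theta.size) / np.sqrt(m_inv)
    h0 = logp - 0.5 * float(rho @ (m_inv * rho))
    _, rho1, logp1, _ = _leapfrog(target, theta, rho, eps, m_inv, grad, 1)
    h1 = logp1 - 0.5 * float(rho1 @ (m_inv * rho1)) if np.isfinite(logp1) else -math.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, rho1, logp1, _ = _leapfrog(target, theta, rho, eps, m_inv, grad, 1)
        h1 = logp1 - 0.5 * float(rho1 @ (m_inv * rho1)) if np.isfinite(logp1) else -math.inf
        if direction * (h1 - h0) < direction * math.log(0.5):
            break
    return eps


@dataclass
class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman-Gelman constants)."""

    mu: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    target: float = 0.8
    t: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    def update(self, accept_prob: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_prob)
        log_eps = self.mu - math.sqrt(self.t) / self.gamma * self.h_bar
        eta = self.t**-self.kappa
        self.log_eps_bar = eta * log_eps + (1 - eta) * self.log_eps_bar
        return math.exp(log_eps)


def _hmc_chain(
    target: _PackedPosterior,
    schedule: MCMCSchedule,
    rng: np.random.Generator,
    target_accept: float,
    max_leapfrog: int,
    max_init_retries: int = 10,
):
    dim = target.dim
    for attempt in range(max_init_retries):
        theta = target.initial(rng)
        logp, grad = target.logp_and_grad(theta)
        if np.isfinite(logp) and np.all(np.isfinite(grad)):
            break
    else:
        raise RuntimeError(
            f"could not find a finite log-posterior initialization in "
            f"{max_init_retries} tries"
        )

    m_inv = np.ones(dim)
    eps = _find_initial_step(target, theta, logp, grad, m_inv, rng)
    da = _DualAveraging(mu=math.log(10.0 * eps), target=target_accept)
    warmup = schedule.warmup
    # mass-adaptation windows (fractions of warmup); each close refits the
    # diagonal mass from the draws inside the window and restarts averaging
    closes = [int(warmup * f) for f in (0.45, 0.85)] if warmup >= 100 else []
    window: list[np.ndarray] = []

    retained = np.empty((schedule.retained, dim))
    n_accept = 0
    for it in range(schedule.iterations):
        rho = rng.standard_normal(dim) / np.sqrt(m_inv)
        h0 = logp - 0.5 * float(rho @ (m_inv * rho))
        n_steps = int(rng.integers(1, max_leapfrog + 1))
        theta_new, rho_new, logp_new, grad_new = _leapfrog(
            target, theta, rho, eps, m_inv, grad, n_steps
        )
        if np.isfinite(logp_new):
            h1 = logp_new - 0.5 * float(rho_new @ (m_inv * rho_new))
            accept_prob = min(1.0, math.exp(min(0.0, h1 - h0)))
        else:
            accept_prob = 0.0
        if rng.random() < accept_prob:
            theta, logp, grad = theta_new, logp_new, grad_new
            if it >= warmup:
                n_accept += 1
        if it < warmup:
            eps = da.update(accept_prob)
            window.append(theta.copy())
            if closes and it + 1 == closes[0]:
                closes.pop(0)
                block = np.asarray(window[len(window) // 4 :])
                if len(block) >= 10:
                    var = block.var(axis=0)
                    n_w = len(block)
                    # regularize toward unit scale as Stan does
                    m_inv = (n_w / (n_w + 5.0)) * var + (5.0 / (n_w + 5.0)) * 1e-3
                    m_inv = np.maximum(m_inv, 1e-10)
                window = []
                eps = _find_initial_step(target, theta, logp, grad, m_inv, rng)
                da = _DualAveraging(mu=math.log(10.0 * eps), target=target_accept)
            if it + 1 == warmup:
                eps = math.exp(da.log_eps_bar)
        else:
            retained[it - warmup] = theta
    accept_rate = n_accept / max(schedule.retained, 1)
    return retained, {"step_size": eps, "accept_rate": accept_rate}


def run_mcmc(
    target: _PackedPosterior,
    schedule: MCMCSchedule | None = None,
    seed: int = 0,
    dims: dict[str, tuple[tuple[str, ...], ...]] | None = None,
    meta: dict | None = None,
    target_accept: float = 0.85,
    max_leapfrog: int = 32,
) -> PosteriorDraws:
    """Sample the posterior of a packed model with adaptive HMC.

    Chains are seeded independently from ``seed`` and run sequentially;
    draws are returned on the natural (constrained) scale via the target's
    ``constrain`` mapping, shaped (chain, draw, *block).
    """
    schedule = schedule or MCMCSchedule()
    seeds = np.random.SeedSequence(seed).spawn(schedule.chains)
    chains = []
    chain_meta = []
    for ss in seeds:
        draws, info = _hmc_chain(
            target, schedule, np.random.default_rng(ss), target_accept, max_leapfrog
        )
        chains.append(draws)
        chain_meta.append(info)
    theta = np.asarray(chains)  # (chain, draw, dim)

    params: dict[str, np.ndarray] = {}
    pos = 0
    for b in target.blocks:
        params[b.name] = theta[:, :, pos : pos + b.size].reshape(
            schedule.chains, schedule.retained, *b.shape
        )
        pos += b.size
    natural = target.constrain(params) if hasattr(target, "constrain") else params
    out_meta = {
        "schedule": schedule,
        "seed": seed,
        "chains": chain_meta,
        **(meta or {}),
    }
    return PosteriorDraws(draws=natural, dims=dims or {}, meta=out_meta)
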