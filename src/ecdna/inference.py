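"""ABC-SMC inference of selection, co-selection and co-segregation.

Given observed single-cell summary statistics of two ecDNA species — the
co-occurrence ``C_obs`` (fraction of cells carrying more than ``m`` copies
of each species) and the Pearson correlation ``rho_obs`` of log-transformed
copy numbers — infer the posterior of

* ``s_indiv``:  selection on cells carrying a single species (the two
  single-species coefficients are tied by default, with an untied option),
  prior Uniform(0, 1);
* ``s_coselect`` (= s_++): co-selection on cells carrying both species,
  prior Uniform(0, 2);
* ``gamma``: the co-segregation coefficient, prior Uniform(0, 1).

Each proposed parameter set is forwarded through the population simulator
(base birth rate 0.5, no death, neutral ecDNA-free cells) and compared with
the observation by the L1 distance ``D = |C_obs - C_0| + |rho_obs - rho_0|``.
The sequential Monte Carlo scheme shrinks the tolerance to the median of the
previous generation's accepted distances until the target ``epsilon`` is
reached, perturbing resampled particles with a component-wise Gaussian
kernel of variance twice the weighted sample variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rng import child_seed, substream
from .segregation import CosegParams
from .simulate import (PopulationSummary, SimulationParams, StopCondition,
                       simulate_leaf_copies, summarize_population)

__all__ = [
    "ObservedStats",
    "ABCConfig",
    "Posterior",
    "abc_distance",
    "sample_prior",
    "prior_bounds",
    "simulate_summary",
    "run_abc_smc",
    "credible_interval",
    "posterior_predictive",
    "resimulate_particles",
    "weighted_quantile",
    "CELL_LINE_TARGETS",
]

#: reported cell-line targets (co-occurrence, log-copy-number correlation)
CELL_LINE_TARGETS = {
    "SNU16m1": (0.99, 0.46),
    "TR14": (0.96, 0.26),
    "GBM39-KT": (0.67, 0.36),
}


@dataclass
class ObservedStats:
    """Observed (C, rho) pair for one sample."""

    c_obs: float
    rho_obs: float
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.c_obs <= 1.0:
            raise ValueError("c_obs must lie in [0, 1]")
        if not -1.0 <= self.rho_obs <= 1.0:
            raise ValueError("rho_obs must lie in [-1, 1]")

    @classmethod
    def cell_line(cls, name: str) -> "ObservedStats":
        c, r = CELL_LINE_TARGETS[name]
        return cls(c, r, label=name)


@dataclass
class ABCConfig:
    """Configuration of one ABC-SMC run.

    ``sim_cells`` trades inference fidelity for runtime (the original
    analysis simulated 500,000 cells per proposal; 20,000 is the desk
    default).  ``m_abc`` is the co-occurrence threshold: cells must carry
    more than ``m_abc`` copies of each species (default 2).
    """

    epsilon_target: float = 0.05
    sim_cells: int = 20_000
    k_init: int = 5
    n_particles: int = 200
    max_generations: int = 15
    max_proposals_factor: int = 50
    tolerance_quantile: float = 0.3
    m_abc: int = 2
    transform: str = "log"
    tied_priors: bool = True
    segregation_model: str = "element_level"
    lambda_base: float = 0.5

    def __post_init__(self):
        if self.epsilon_target <= 0:
            raise ValueError("epsilon_target must be positive")
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")

    @property
    def param_names(self) -> list[str]:
        if self.tied_priors:
            return ["s_indiv", "s_coselect", "gamma"]
        return ["s_minus_plus", "s_plus_minus", "s_coselect", "gamma"]


def prior_bounds(config: ABCConfig) -> np.ndarray:
    """Uniform prior support per parameter, shape (n_params, 2)."""
    if config.tied_priors:
        return np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 1.0]])
    return np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 2.0], [0.0, 1.0]])


def sample_prior(config: ABCConfig, rng) -> np.ndarray:
    """One draw from the joint uniform prior."""
    b = prior_bounds(config)
    return rng.uniform(b[:, 0], b[:, 1])


def abc_distance(obs: ObservedStats, sim: PopulationSummary) -> float:
    """L1 distance ``|C_obs - C_0| + |rho_obs - rho_0|``; infinite when the
    simulated correlation is undefined (degenerate population)."""
    if not sim.correlation_defined:
        return math.inf
    return abs(obs.c_obs - sim.co_occurrence) + abs(obs.rho_obs - sim.correlation)


def _theta_to_params(theta: np.ndarray, config: ABCConfig, seed: int) -> SimulationParams:
    if config.tied_priors:
        s_mp = s_pm = float(theta[0])
        s_pp, gamma = float(theta[1]), float(theta[2])
    else:
        s_mp, s_pm = float(theta[0]), float(theta[1])
        s_pp, gamma = float(theta[2]), float(theta[3])
    return SimulationParams(
        k_init=(config.k_init, config.k_init),
        s_minus_minus=0.0, s_minus_plus=s_mp, s_plus_minus=s_pm,
        s_plus_plus=s_pp, lambda_base=config.lambda_base, death_rate=0.0,
        coseg=CosegParams(gamma=gamma, model=config.segregation_model),
        stop=StopCondition(target_cells=config.sim_cells), seed=seed)


def simulate_summary(theta: np.ndarray, config: ABCConfig, seed: int) -> PopulationSummary | None:
    """Simulate one population at ``theta`` and summarize it; ``None`` on
    extinction (no death here, so only a defensive branch)."""
    params = _theta_to_params(theta, config, seed)
    leaves, extinct = simulate_leaf_copies(params)
    if extinct or leaves.shape[0] < 2:
        return None
    return summarize_population(leaves, m=config.m_abc, transform=config.transform)


@dataclass
class Posterior:
    """Weighted particles after the final SMC generation."""

    particles: pd.DataFrame  # param columns + weight + distance
    param_names: list[str]
    achieved_tolerance: float
    tolerances: list[float]
    converged: bool
    n_simulations: int
    config: ABCConfig
    obs: ObservedStats

    def draws(self, n: int, rng) -> np.ndarray:
        """Sample ``n`` parameter vectors from the weighted particles."""
        idx = rng.choice(len(self.particles), size=n, p=self.particles["weight"].to_numpy())
        return self.particles[self.param_names].to_numpy()[idx]

    def mean(self) -> pd.Series:
        w = self.particles["weight"].to_numpy()
        th = self.particles[self.param_names].to_numpy()
        return pd.Series((th * w[:, None]).sum(axis=0), index=self.param_names)


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Quantile(s) of a weighted sample (step-function inverse CDF: the
    smallest value whose cumulative weight reaches ``q``)."""
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cdf = np.cumsum(w) / np.sum(w)
    idx = np.searchsorted(cdf, np.atleast_1d(q), side="left")
    return v[np.clip(idx, 0, v.shape[0] - 1)]


def credible_interval(posterior: Posterior, level: float = 0.95) -> pd.DataFrame:
    """Central weighted-quantile credible interval per parameter."""
    if len(posterior.particles) < 1:
        raise ValueError("empty posterior")
    if len(posterior.particles) == 1:
        import warnings
        warnings.warn("single-particle posterior: degenerate interval")
    alpha = (1.0 - level) / 2.0
    rows = {}
    w = posterior.particles["weight"].to_numpy()
    for name in posterior.param_names:
        v = posterior.particles[name].to_numpy()
        lo, hi = weighted_quantile(v, w, [alpha, 1.0 - alpha])
        rows[name] = {"lower": lo, "upper": hi}
    return pd.DataFrame(rows).T


class ToleranceStallError(RuntimeError):
    """No proposals were accepted within the per-generation budget."""


def run_abc_smc(obs: ObservedStats, config: ABCConfig, seed: int = 0,
                verbose: bool = False) -> Posterior:
    """Run ABC-SMC until ``epsilon_target`` is reached or budgets exhaust.

    Returns the weighted posterior; ``converged`` is False when the budget
    ran out first (the achieved tolerance is reported either way).
    """
    rng = substream(seed, "abc", obs.label)
    bounds = prior_bounds(config)
    n_params = bounds.shape[0]
    N = config.n_particles
    max_props = config.max_proposals_factor * N
    sim_counter = 0

    def simulate_distance(theta):
        nonlocal sim_counter
        s = child_seed(seed, "abc-sim", obs.label, sim_counter)
        sim_counter += 1
        summary = simulate_summary(theta, config, s)
        d = math.inf if summary is None else abc_distance(obs, summary)
        return d, s

    # generation 0: accept the first N finite-distance prior draws
    thetas = np.empty((N, n_params))
    dists = np.empty(N)
    seeds = np.empty(N, dtype=np.int64)
    accepted = 0
    proposals = 0
    while accepted < N:
        if proposals >= max_props:
            raise ToleranceStallError(
                f"generation 0 stalled: {accepted}/{N} finite-distance draws "
                f"in {proposals} proposals")
        theta = sample_prior(config, rng)
        d, s = simulate_distance(theta)
        proposals += 1
        if math.isfinite(d):
            thetas[accepted] = theta
            dists[accepted] = d
            seeds[accepted] = s
            accepted += 1
    weights = np.full(N, 1.0 / N)
    tolerances: list[float] = []
    tol = math.inf
    converged = False

    for gen in range(1, config.max_generations + 1):
        new_tol = float(np.quantile(dists, config.tolerance_quantile))
        if not new_tol < tol:
            break  # schedule stalled at the stochastic floor
        tol = max(new_tol, config.epsilon_target)
        sigma = np.sqrt(2.0 * np.average(
            (thetas - np.average(thetas, axis=0, weights=weights)) ** 2,
            axis=0, weights=weights))
        sigma = np.maximum(sigma, 1e-6)

        new_thetas = np.empty((N, n_params))
        new_dists = np.empty(N)
        new_seeds = np.empty(N, dtype=np.int64)
        accepted = 0
        proposals = 0
        while accepted < N and proposals < max_props:
            j = rng.choice(N, p=weights)
            for _ in range(100):
                cand = thetas[j] + rng.normal(0.0, sigma)
                if np.all((cand >= bounds[:, 0]) & (cand <= bounds[:, 1])):
                    break
            else:
                proposals += 1
                continue
            d, s = simulate_distance(cand)
            proposals += 1
            if d <= tol:
                new_thetas[accepted] = cand
                new_dists[accepted] = d
                new_seeds[accepted] = s
                accepted += 1
        if accepted == 0:
            raise ToleranceStallError(
                f"generation {gen} (tolerance {tol:.4g}) accepted 0 of "
                f"{proposals} proposals; achieved tolerance "
                f"{tolerances[-1] if tolerances else float('inf'):.4g}")
        new_thetas = new_thetas[:accepted]
        new_dists = new_dists[:accepted]
        new_seeds = new_seeds[:accepted]

        # importance weights: uniform prior => 1 / sum_j w_j K(theta | theta_j)
        diff = (new_thetas[:, None, :] - thetas[None, :, :]) / sigma
        log_k = -0.5 * np.sum(diff ** 2, axis=2)
        log_k -= np.sum(np.log(sigma)) + 0.5 * n_params * math.log(2 * math.pi)
        denom = np.einsum("ij,j->i", np.exp(log_k), weights)
        new_weights = 1.0 / np.maximum(denom, 1e-300)
        new_weights /= new_weights.sum()

        thetas, dists, weights, seeds = new_thetas, new_dists, new_weights, new_seeds
        tolerances.append(tol)
        if verbose:
            print(f"gen {gen}: tol={tol:.4f} accepted={accepted} "
                  f"proposals={proposals} sims={sim_counter}")
        if accepted < N:
            break  # proposal budget exhausted mid-generation
        if tol <= config.epsilon_target:
            converged = True
            break

    particles = pd.DataFrame(thetas, columns=config.param_names)
    particles["weight"] = weights
    particles["distance"] = dists
    particles["sim_seed"] = seeds
    return Posterior(
        particles=particles, param_names=config.param_names,
        achieved_tolerance=tol if tolerances else math.inf,
        tolerances=tolerances, converged=converged,
        n_simulations=sim_counter, config=config, obs=obs)


def resimulate_particles(posterior: Posterior, n: int = 20,
                         seed: int = 0) -> pd.DataFrame:
    """Re-simulate ``n`` accepted particles with their stored seeds.

    Verifies the acceptance guarantee: each particle's (C, rho) — and hence
    its distance to the observation — is exactly reproduced, so every
    re-simulated statistic deviates from the target by at most the particle's
    accepted distance.
    """
    rng = substream(seed, "abc-resim")
    n = min(n, len(posterior.particles))
    idx = rng.choice(len(posterior.particles), size=n, replace=False)
    rows = []
    for i in idx:
        row = posterior.particles.iloc[int(i)]
        theta = row[posterior.param_names].to_numpy(dtype=float)
        summary = simulate_summary(theta, posterior.config, int(row["sim_seed"]))
        rows.append({
            "c_sim": summary.co_occurrence,
            "rho_sim": summary.correlation,
            "distance_stored": row["distance"],
            "distance_resim": abc_distance(posterior.obs, summary),
        })
    return pd.DataFrame(rows)


def posterior_predictive(posterior: Posterior, n_draws: int = 20,
                         seed: int = 0) -> pd.DataFrame:
    """Re-simulate populations at posterior draws; returns per-draw (C, rho)."""
    rng = substream(seed, "abc-ppc")
    thetas = posterior.draws(n_draws, rng)
    rows = []
    for i, theta in enumerate(thetas):
        summary = simulate_summary(theta, posterior.config,
                                   child_seed(seed, "abc-ppc-sim", i))
        if summary is None:
            continue
        row = {name: theta[j] for j, name in enumerate(posterior.param_names)}
        row["c_sim"] = summary.co_occurrence
        row["rho_sim"] = summary.correlation
        rows.append(row)
    return pd.DataFrame(rows)
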