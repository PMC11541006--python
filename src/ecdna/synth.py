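"""Synthetic data generators with ground-truth sidecars.

Every downstream analysis in this package can be exercised without any
external download: these generators emit (i) windowed single-cell insertion
count matrices with GC-dependent background and embedded focal
amplifications whose per-cell copy numbers follow a chosen source (the
population simulator for realistic overdispersed, correlated ecDNA copy
numbers; a constant for HSR-like amplifications; a negative binomial for
parametric control), (ii) daughter-pair signal tables emulating FISH
measurements with multiplicative lognormal noise, and (iii) observed
summary-statistic pairs for ABC parameter-recovery studies.

Each generator is deterministic given its seed and returns a
machine-readable truth record; validations compare against that record,
never against hard-coded expectations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import __version__
from .inference import ObservedStats
from .rng import child_seed, substream
from .segregation import CosegParams, sample_divisions, CopyState
from .simulate import (SimulationParams, StopCondition, simulate_leaf_copies,
                       summarize_population)
from .pairs import PairSet

__all__ = [
    "AmpliconSpec",
    "SyntheticCounts",
    "gen_counts_matrix",
    "cn_profile_fixed",
    "cn_profile_nbinom",
    "cn_profiles_from_simulation",
    "gen_daughter_pairs",
    "gen_observed_stats",
]


def cn_profile_fixed(n_cells: int, value: float) -> np.ndarray:
    """Constant per-cell copy number (HSR-like: no cell-to-cell variance)."""
    return np.full(n_cells, float(value))


def cn_profile_nbinom(n_cells: int, mean: float, var_mean_ratio: float, rng) -> np.ndarray:
    """Negative-binomial per-cell copy number with a stated variance/mean
    ratio (> 1); parametric stand-in for ecDNA-like overdispersion."""
    if var_mean_ratio <= 1.0:
        raise ValueError("negative binomial needs variance/mean > 1")
    r = mean / (var_mean_ratio - 1.0)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n_cells).astype(float)


def cn_profiles_from_simulation(n_cells: int, seed: int,
                                params: SimulationParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell copy numbers of two species sampled from simulator leaves.

    Default population: both species selected (s_indiv 0.2, s_++ 1.0),
    gamma from ``params.coseg`` (default 1.0) — yields the correlated,
    overdispersed copy-number distributions characteristic of co-inherited
    ecDNA.
    """
    if params is None:
        params = SimulationParams(
            k_init=(10, 10), s_minus_plus=0.2, s_plus_minus=0.2,
            s_plus_plus=1.0, coseg=CosegParams(gamma=1.0),
            stop=StopCondition(target_cells=max(2 * n_cells, 2000)))
    leaves, extinct = simulate_leaf_copies(params, seed=seed)
    if extinct or leaves.shape[0] < n_cells:
        raise RuntimeError("simulated population too small for the request")
    rng = substream(seed, "leaf-sample")
    idx = rng.choice(leaves.shape[0], size=n_cells, replace=False)
    return leaves[idx, 0].astype(float), leaves[idx, 1].astype(float)


@dataclass
class AmpliconSpec:
    """A focal amplification embedded in the synthetic matrix.

    ``window_lo:window_hi`` is the half-open range of window rows the
    amplicon spans; ``cn`` the per-cell copy number on a diploid baseline.
    """

    window_lo: int
    window_hi: int
    cn: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.cn = np.asarray(self.cn, dtype=float)
        if self.window_hi <= self.window_lo:
            raise ValueError("empty amplicon window range")
        if np.any(self.cn < 0):
            raise ValueError("copy numbers must be non-negative")


@dataclass
class SyntheticCounts:
    """Synthetic windowed count matrix plus its ground truth."""

    counts: sp.csr_matrix
    windows: pd.DataFrame
    cell_ids: np.ndarray
    truth: dict = field(default_factory=dict)

    def write(self, outdir):
        from .cnquant import write_window_counts
        import os

        write_window_counts(outdir, self.counts, self.windows, self.cell_ids)
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=1,
                      default=lambda o: o.tolist() if isinstance(o, np.ndarray) else o)


def gen_counts_matrix(n_cells: int = 500, n_windows: int = 1500,
                      amplicons: list[AmpliconSpec] | None = None,
                      depth: int = 5000, gc_coeffs: tuple[float, float] = (1.5, -6.0),
                      window: int = 3_000_000, step: int = 1_000_000,
                      seed: int = 0) -> SyntheticCounts:
    """Windowed insertion counts with GC-dependent background.

    Background rates follow a quadratic log-rate GC curve
    ``exp(a*(gc-0.45) + b*(gc-0.45)^2)``; amplified windows are scaled by
    the spec's per-cell ``CN/2``.  Expected total insertions per cell is
    ``depth`` (sparse, scATAC-like).  GC content varies smoothly along the
    synthetic chromosome, as it does along real genomes.
    """
    amplicons = amplicons or []
    rng = substream(seed, "counts")
    # overlap check
    used = np.zeros(n_windows, dtype=bool)
    for spec in amplicons:
        if spec.window_hi > n_windows:
            raise ValueError("amplicon outside the window range")
        if used[spec.window_lo:spec.window_hi].any():
            raise ValueError("overlapping amplicon specs")
        used[spec.window_lo:spec.window_hi] = True
        if spec.cn.shape[0] != n_cells:
            raise ValueError("amplicon cn must have one value per cell")

    pos = np.arange(n_windows)
    gc = (0.45 + 0.07 * np.sin(2 * np.pi * pos / 149.0)
          + 0.015 * rng.standard_normal(n_windows))
    gc = np.clip(gc, 0.30, 0.62)
    windows = pd.DataFrame({
        "chrom": "chrS",
        "start": pos * step,
        "end": pos * step + window,
        "gc": gc,
        "blacklisted": False,
    })

    a, b = gc_coeffs
    base = np.exp(a * (gc - 0.45) + b * (gc - 0.45) ** 2)
    weight = np.tile(base, (n_cells, 1))
    for spec in amplicons:
        weight[:, spec.window_lo:spec.window_hi] *= (spec.cn[:, None] / 2.0)
    rate = depth * weight / weight.sum(axis=1, keepdims=True)
    counts = rng.poisson(rate)

    truth = {
        "generator": "gen_counts_matrix",
        "version": __version__,
        "seed": int(seed),
        "n_cells": int(n_cells),
        "n_windows": int(n_windows),
        "depth": int(depth),
        "gc_coeffs": [float(a), float(b)],
        "amplicons": [
            {"label": s.label, "window_lo": int(s.window_lo),
             "window_hi": int(s.window_hi), "cn": s.cn.tolist()}
            for s in amplicons
        ],
    }
    cell_ids = np.array([f"cell{i:05d}" for i in range(n_cells)])
    return SyntheticCounts(counts=sp.csr_matrix(counts), windows=windows,
                           cell_ids=cell_ids, truth=truth)


def gen_daughter_pairs(n_pairs: int, copies: tuple[int, int] = (30, 30),
                       coseg: CosegParams | None = None,
                       fusion_fraction: float = 0.0,
                       noise_sd: float = 0.1,
                       condition: str = "synthetic",
                       seed: int = 0) -> tuple[PairSet, dict]:
    """Simulated daughter-pair FISH measurements.

    Divisions of a parent with ``copies`` follow the requested segregation
    rule; daughter copy numbers become signals through multiplicative
    lognormal measurement noise (sd of log-signal ``noise_sd``).  Returns
    the pair set and its truth record.
    """
    coseg = coseg or CosegParams(model="fraction_coupled", coupled_fraction=0.5)
    rng = substream(seed, "pairs")
    parent = CopyState(np.asarray(copies, dtype=np.int64))
    if n_pairs > 0:
        d1, d2 = sample_divisions(parent, coseg, n_pairs, rng)
        noise = np.exp(noise_sd * rng.standard_normal((n_pairs, 4))) if noise_sd > 0 \
            else np.ones((n_pairs, 4))
        frame = pd.DataFrame({
            "pair_id": [f"pair{i:05d}" for i in range(n_pairs)],
            "s1_d1": d1[:, 0] * noise[:, 0],
            "s1_d2": d2[:, 0] * noise[:, 1],
            "s2_d1": d1[:, 1] * noise[:, 2],
            "s2_d2": d2[:, 1] * noise[:, 3],
            "fusion_fraction": fusion_fraction,
            "condition": condition,
        })
    else:
        frame = pd.DataFrame(columns=PairSet.COLUMNS)
    truth = {
        "generator": "gen_daughter_pairs",
        "version": __version__,
        "seed": int(seed),
        "copies": [int(c) for c in copies],
        "model": coseg.model,
        "gamma": coseg.gamma,
        "coupled_fraction": coseg.coupled_fraction,
        "fusion_fraction": float(fusion_fraction),
        "noise_sd": float(noise_sd),
        "n_pairs": int(n_pairs),
    }
    return PairSet(frame), truth


def gen_observed_stats(theta_true, sim_cells: int = 20_000, k_init: int = 5,
                       m_abc: int = 2, transform: str = "log",
                       seed: int = 0, label: str = "synthetic",
                       max_retries: int = 10) -> tuple[ObservedStats, dict]:
    """Observed (C, rho) generated at a known parameter vector.

    ``theta_true`` is ``(s_indiv, s_coselect, gamma)``.  Used to create
    recovery targets for ABC; the truth record carries the generating
    parameters.  Extinct simulations (impossible without death, defensive
    only) are retried on a fresh substream.
    """
    s_indiv, s_pp, gamma = (float(x) for x in theta_true)
    retries = 0
    for attempt in range(max_retries):
        params = SimulationParams(
            k_init=(k_init, k_init), s_minus_minus=0.0,
            s_minus_plus=s_indiv, s_plus_minus=s_indiv, s_plus_plus=s_pp,
            lambda_base=0.5, death_rate=0.0,
            coseg=CosegParams(gamma=gamma),
            stop=StopCondition(target_cells=sim_cells),
            seed=child_seed(seed, "obs", attempt))
        leaves, extinct = simulate_leaf_copies(params)
        if not extinct and leaves.shape[0] >= 2:
            break
        retries += 1
    else:
        raise RuntimeError("observed-stats simulation kept going extinct")
    summ = summarize_population(leaves, m=m_abc, transform=transform)
    obs = ObservedStats(summ.co_occurrence,
                        summ.correlation if summ.correlation_defined else 0.0,
                        label=label)
    truth = {
        "generator": "gen_observed_stats",
        "version": __version__,
        "seed": int(seed),
        "theta_true": {"s_indiv": s_indiv, "s_coselect": s_pp, "gamma": gamma},
        "sim_cells": int(sim_cells),
        "k_init": int(k_init),
        "m_abc": int(m_abc),
        "transform": transform,
        "retries": retries,
        "c_obs": obs.c_obs,
        "rho_obs": obs.rho_obs,
    }
    return obs, truth
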