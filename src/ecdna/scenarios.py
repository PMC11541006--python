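"""Multi-phase treatment and sweep scenarios.

A :class:`TreatmentSchedule` chains population-simulation phases on one
global clock: each phase may override selection coefficients, the base birth
rate or the death rate (drug on/off), optionally bottleneck the population
(random sampling without replacement) before it starts, and stops at its own
cell-count or global-time target.  The per-phase event stream is reduced to
time-binned mean copy numbers per species — the copy-number trajectories
used to study targeted-drug dynamics of co-existing ecDNA species.

``preset_pemigatinib_pulse`` encodes the reference pulsed-treatment
schedule for an FGFR2/MYC double-ecDNA line: burn-in to 5,000 cells,
FGFR2-targeted treatment (selection on FGFR2-carrying cells flipped to
-0.1) to 100,000 cells, a drug holiday (original selection, slower base
birth rate 0.4) to 1.2 million cells, and re-treatment until global time
110; bottlenecks of 25,000 and 200,000 cells seed the holiday and the
re-treatment.  All cell counts shrink by ``scale`` for desk execution.

Note on the death parameter: the reference schedule specifies a death
parameter of 2.5 alongside a base birth rate of 0.5; as a hazard rate that
would make every cell class strongly subcritical and the schedule's growth
targets unreachable, so it is interpreted as the mean waiting time to death
(exponential scale), i.e. a hazard of ``1/2.5 = 0.4``.  The preset exposes
the stated value as ``meta['death_mean_waiting_time']``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .rng import child_seed, substream
from .segregation import CosegParams
from .simulate import (SimulationParams, StopCondition, _run_kernel,
                       summarize_population)

__all__ = [
    "PhaseSpec",
    "TreatmentSchedule",
    "TrajectoryReport",
    "run_schedule",
    "preset_pemigatinib_pulse",
    "preset_enhancer_base",
    "sweep_grid",
]

_OVERRIDE_FIELDS = ("s_minus_minus", "s_minus_plus", "s_plus_minus",
                    "s_plus_plus", "lambda_base", "death_rate")


@dataclass
class PhaseSpec:
    """One phase of a schedule; ``None`` overrides inherit the base value."""

    name: str
    stop: StopCondition
    s_minus_minus: float | None = None
    s_minus_plus: float | None = None
    s_plus_minus: float | None = None
    s_plus_plus: float | None = None
    lambda_base: float | None = None
    death_rate: float | None = None
    bottleneck_sample: int | None = None
    bin_width: float = 1.0
    #: restart the phase from its starting population on extinction (used
    #: for establishment phases, conditioning on lineage survival); later
    #: extinctions are results, not conditioning
    retry_on_extinction: bool = False
    max_retries: int = 200

    def apply_to(self, base: SimulationParams) -> SimulationParams:
        overrides = {f: getattr(self, f) for f in _OVERRIDE_FIELDS
                     if getattr(self, f) is not None}
        return replace(base, stop=self.stop, **overrides)


@dataclass
class TreatmentSchedule:
    base: SimulationParams
    phases: list[PhaseSpec]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.phases:
            raise ValueError("schedule needs at least one phase")


@dataclass
class TrajectoryReport:
    """Time-binned mean copy numbers per species along a schedule.

    ``trajectory`` columns: bin_start, bin_end, phase, mean_cn1, mean_cn2,
    n_cells.  ``phase_bounds`` records start/end time and population size of
    each executed phase.  ``extinct`` marks a schedule truncated by
    population extinction.
    """

    trajectory: pd.DataFrame
    phase_bounds: pd.DataFrame
    final_population: np.ndarray
    final_time: float
    extinct: bool

    def phase_slice(self, name: str) -> pd.DataFrame:
        return self.trajectory[self.trajectory["phase"] == name]


def _bin_phase(events: pd.DataFrame, t_start: float, t_end: float,
               width: float, name: str) -> pd.DataFrame:
    edges = np.arange(t_start, t_end + width, width)
    if len(edges) < 2:
        edges = np.array([t_start, t_end])
    rows = []
    idx = np.searchsorted(edges, events["time"].to_numpy(), side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            rows.append({
                "bin_start": edges[b], "bin_end": edges[b + 1], "phase": name,
                "mean_cn1": float(events["mean_cn1"].to_numpy()[sel].mean()),
                "mean_cn2": float(events["mean_cn2"].to_numpy()[sel].mean()),
                "n_cells": int(events["n_cells"].to_numpy()[sel][-1]),
            })
        elif rows:
            prev = rows[-1]
            rows.append({**prev, "bin_start": edges[b], "bin_end": edges[b + 1]})
    return pd.DataFrame(rows)


def run_schedule(schedule: TreatmentSchedule, seed: int = 0,
                 max_cells: int | None = None) -> TrajectoryReport:
    """Execute the phases sequentially on one global clock.

    The surviving cells of each phase (after the next phase's optional
    bottleneck) seed the next phase.  Reproducible from ``seed``.
    """
    base = schedule.base
    k1 = np.array([base.k_init[0]], dtype=np.int64)
    k2 = np.array([base.k_init[1]], dtype=np.int64)
    t = 0.0
    extinct = False
    traj_parts = []
    bounds = []

    for i, phase in enumerate(schedule.phases):
        if phase.bottleneck_sample is not None:
            if phase.bottleneck_sample > k1.shape[0]:
                raise ValueError(
                    f"bottleneck {phase.bottleneck_sample} exceeds population "
                    f"size {k1.shape[0]} at start of phase {phase.name!r}")
            rng = substream(seed, "bottleneck", i)
            keep = rng.choice(k1.shape[0], size=phase.bottleneck_sample,
                              replace=False)
            k1, k2 = k1[keep], k2[keep]

        params = phase.apply_to(base)
        cap = max_cells
        if cap is None and params.stop.target_cells is None:
            cap = max(1_000_000, 50 * k1.shape[0])
        t_start = t
        n_start = k1.shape[0]
        attempt = 0
        while True:
            status, t_new, leaf_copies, _, events = _run_kernel(
                params, child_seed(seed, "schedule-phase", i, attempt),
                _kernels.REC_TRAJ, k1, k2, t_start, cap)
            if (status != _kernels.STATUS_EXTINCT or not phase.retry_on_extinction
                    or attempt >= phase.max_retries):
                break
            attempt += 1
        t = t_new
        k1 = leaf_copies[:, 0]
        k2 = leaf_copies[:, 1]
        t_end = t if events is None or not len(events) else max(t, events["time"].iloc[-1])
        if len(events):
            traj_parts.append(_bin_phase(events, t_start, t_end,
                                         phase.bin_width, phase.name))
        bounds.append({"phase": phase.name, "t_start": t_start, "t_end": t,
                       "n_start": n_start, "n_end": k1.shape[0]})
        if status == _kernels.STATUS_EXTINCT:
            extinct = True
            break

    trajectory = (pd.concat(traj_parts, ignore_index=True)
                  if traj_parts else pd.DataFrame(
                      columns=["bin_start", "bin_end", "phase",
                               "mean_cn1", "mean_cn2", "n_cells"]))
    return TrajectoryReport(
        trajectory=trajectory, phase_bounds=pd.DataFrame(bounds),
        final_population=np.stack([k1, k2], axis=1) if k1.shape[0] else np.zeros((0, 2), np.int64),
        final_time=t, extinct=extinct)


def preset_pemigatinib_pulse(gamma: float = 0.9, scale: float = 0.1,
                             k_init: tuple[int, int] = (10, 10),
                             model: str = "element_level") -> TreatmentSchedule:
    """Published pulsed FGFR2-inhibitor schedule (species 1 = FGFR2 ecDNA,
    species 2 = MYC ecDNA); cell-count targets shrink by ``scale``."""

    def cells(n):
        return max(2, int(round(n * scale)))

    death_mean_wait = 2.5
    base = SimulationParams(
        k_init=k_init, lambda_base=0.5, death_rate=1.0 / death_mean_wait,
        s_minus_minus=0.0, s_minus_plus=0.15, s_plus_minus=0.15,
        s_plus_plus=0.8,
        coseg=CosegParams(gamma=gamma, model=model),
        stop=StopCondition(target_cells=cells(5_000)))
    phases = [
        PhaseSpec("burn_in", StopCondition(target_cells=cells(5_000)),
                  bin_width=5.0, retry_on_extinction=True),
        PhaseSpec("treatment_1", StopCondition(target_cells=cells(100_000)),
                  s_plus_plus=-0.1, s_plus_minus=-0.1, bin_width=1.0),
        PhaseSpec("holiday", StopCondition(target_cells=cells(1_200_000)),
                  lambda_base=0.4, bottleneck_sample=cells(25_000),
                  bin_width=1.0),
        PhaseSpec("treatment_2", StopCondition(target_time=110.0),
                  s_plus_plus=-0.1, s_plus_minus=-0.1,
                  bottleneck_sample=cells(200_000), bin_width=1.0),
    ]
    return TreatmentSchedule(
        base=base, phases=phases,
        meta={"death_mean_waiting_time": death_mean_wait,
              "scale": scale, "preset": "pemigatinib-pulse"})


def preset_enhancer_base(gamma: float = 0.5, s_plus_plus: float = 0.0,
                         model: str = "element_level") -> SimulationParams:
    """Enhancer-only ecDNA base parameters: species 1 carries the oncogene
    (selected alone, s=0.2), species 2 only enhancers (neutral alone)."""
    return SimulationParams(
        k_init=(5, 5), lambda_base=0.5, death_rate=0.0,
        s_minus_minus=0.0, s_plus_minus=0.2, s_minus_plus=0.0,
        s_plus_plus=s_plus_plus,
        coseg=CosegParams(gamma=gamma, model=model),
        stop=StopCondition(target_cells=10_000))


def sweep_grid(base: SimulationParams,
               gammas,
               s_plus_plus_values=None,
               treatment_s_values=None,
               replicates: int = 10,
               target_cells: int = 10_000,
               burn_in_cells: int = 500,
               m: int = 1,
               transform: str = "raw",
               seed: int = 0) -> pd.DataFrame:
    """Replicated simulations over a (gamma x selection) grid.

    With ``s_plus_plus_values`` each grid point grows a fresh population to
    ``target_cells`` under co-selection ``s_++`` (co-assortment and
    enhancer-only sweeps).  With ``treatment_s_values`` each point first
    burns in to ``burn_in_cells`` under the base parameters, then applies
    ``s_++ = s_+- = s`` (drug pressure on species-1 carriers) until
    ``target_cells``.  One row per (grid point, replicate) with the
    population summary statistics.
    """
    if (s_plus_plus_values is None) == (treatment_s_values is None):
        raise ValueError("give exactly one of s_plus_plus_values / treatment_s_values")
    svals = s_plus_plus_values if s_plus_plus_values is not None else treatment_s_values
    mode = "growth" if s_plus_plus_values is not None else "treatment"
    rows = []
    for g in gammas:
        for s in svals:
            for rep in range(replicates):
                rep_seed = child_seed(seed, "sweep", mode, round(float(g), 6),
                                      round(float(s), 6), rep)
                if mode == "growth":
                    params = replace(
                        base, s_plus_plus=float(s),
                        coseg=replace(base.coseg, gamma=float(g)),
                        stop=StopCondition(target_cells=target_cells),
                        seed=rep_seed)
                    schedule = TreatmentSchedule(base=params, phases=[
                        PhaseSpec("growth", params.stop)])
                else:
                    params = replace(
                        base, coseg=replace(base.coseg, gamma=float(g)),
                        stop=StopCondition(target_cells=burn_in_cells),
                        seed=rep_seed)
                    schedule = TreatmentSchedule(base=params, phases=[
                        PhaseSpec("burn_in", StopCondition(target_cells=burn_in_cells),
                                  retry_on_extinction=True),
                        PhaseSpec("treatment", StopCondition(target_cells=target_cells),
                                  s_plus_plus=float(s), s_plus_minus=float(s)),
                    ])
                report = run_schedule(schedule, seed=rep_seed)
                row = {"gamma": float(g),
                       ("s_plus_plus" if mode == "growth" else "treatment_s"): float(s),
                       "replicate": rep, "extinct": report.extinct}
                if report.extinct or report.final_population.shape[0] < 2:
                    row.update({"C": np.nan, "rho": np.nan, "pure": np.nan,
                                "mix": np.nan, "free": np.nan,
                                "mean_cn1": np.nan, "mean_cn2": np.nan})
                else:
                    summ = summarize_population(report.final_population, m=m,
                                                transform=transform)
                    row.update({
                        "C": summ.co_occurrence,
                        "rho": summ.correlation if summ.correlation_defined else np.nan,
                        "pure": summ.pure, "mix": summ.mix, "free": summ.free,
                        "mean_cn1": float(summ.mean_cn[0]),
                        "mean_cn2": float(summ.mean_cn[1])})
                rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["gamma", "s_plus_plus" if mode == "growth" else "treatment_s",
                                     "replicate", "extinct", "C", "rho", "pure",
                                     "mix", "free", "mean_cn1", "mean_cn2"])
    return pd.DataFrame(rows)
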