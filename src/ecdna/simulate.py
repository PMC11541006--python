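"""Forward-time birth-death simulation of ecDNA-carrying cell populations.

A population is founded by cells carrying two ecDNA species.  Each cell
divides at rate ``lambda_base * (1 + s)``, where the selection coefficient
``s`` is chosen from ``{s_--, s_-+, s_+-, s_++}`` by which species are
present (copy number > 0), and optionally dies at rate ``death_rate``.
Waiting times are exponential, so the population follows an exact
continuous-time Gillespie process.  At every division the doubled copies are
partitioned between the daughters by one of the segregation rules in
:mod:`ecdna.segregation`.

The simulation stops at a target cell count or a target time, whichever
comes first; cells mid-waiting-time at the stop are counted as leaves with
their current copy state.  The full lineage can optionally be retained as a
:class:`LineageTree` (with Newick export) for modest population sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .rng import child_seed
from .segregation import MODELS, CopyState, CosegParams

__all__ = [
    "StopCondition",
    "SimulationParams",
    "PopulationSummary",
    "PopulationResult",
    "LineageTree",
    "compute_birth_rate",
    "DivisionEvent",
    "draw_division_event",
    "selection_coefficient",
    "simulate_population",
    "simulate_leaf_copies",
    "summarize_population",
    "subpopulation_fractions",
]

_MODEL_CODES = {name: i for i, name in enumerate(MODELS)}

#: retaining the full lineage above this leaf count is refused
TREE_LEAF_CAP = 200_000


@dataclass
class StopCondition:
    """Stop at ``target_cells`` or ``target_time``, whichever is reached first."""

    target_cells: int | None = None
    target_time: float | None = None

    def __post_init__(self):
        if self.target_cells is None and self.target_time is None:
            raise ValueError("set target_cells and/or target_time")
        if self.target_cells is not None and self.target_cells < 1:
            raise ValueError("target_cells must be positive")
        if self.target_time is not None and self.target_time <= 0:
            raise ValueError("target_time must be positive")


@dataclass
class SimulationParams:
    """Evolutionary parameters of one population simulation.

    Selection coefficients are additive fitness effects on the birth rate:
    ``s_minus_minus`` acts on cells with neither species, ``s_plus_minus`` /
    ``s_minus_plus`` on cells with only species 1 / only species 2, and
    ``s_plus_plus`` (co-selection) on cells carrying both.  ``death_rate``
    is the hazard of cell death per unit time (0 disables death).
    """

    k_init: tuple[int, int] = (5, 5)
    s_minus_minus: float = 0.0
    s_minus_plus: float = 0.0
    s_plus_minus: float = 0.0
    s_plus_plus: float = 0.0
    lambda_base: float = 0.5
    death_rate: float = 0.0
    coseg: CosegParams = field(default_factory=CosegParams)
    stop: StopCondition = field(default_factory=lambda: StopCondition(target_cells=1000))
    seed: int = 0

    def __post_init__(self):
        if self.lambda_base <= 0:
            raise ValueError("lambda_base must be positive")
        if self.death_rate < 0:
            raise ValueError("death_rate must be non-negative")
        if len(self.k_init) != 2 or any(k < 0 for k in self.k_init):
            raise ValueError("k_init must be two non-negative integers")
        for name in ("s_minus_minus", "s_minus_plus", "s_plus_minus", "s_plus_plus"):
            if 1.0 + getattr(self, name) <= 0.0:
                raise ValueError(f"{name} implies a non-positive birth rate")


def selection_coefficient(state, params: SimulationParams) -> float:
    """Selection coefficient acting on a cell, from presence of each species."""
    k = state.copies if isinstance(state, CopyState) else np.asarray(state)
    has1, has2 = k[0] > 0, k[1] > 0
    if has1 and has2:
        return params.s_plus_plus
    if has1:
        return params.s_plus_minus
    if has2:
        return params.s_minus_plus
    return params.s_minus_minus


def compute_birth_rate(state, params: SimulationParams) -> float:
    """Realized birth rate ``lambda_1 = lambda_base * (1 + s)`` of a cell."""
    s = selection_coefficient(state, params)
    lam = params.lambda_base * (1.0 + s)
    if lam <= 0:
        raise ValueError("birth rate must be positive (1 + s <= 0)")
    return lam


@dataclass
class DivisionEvent:
    """One cell's realized rate and waiting-time draws.

    ``t_death`` is None when no death rate is set; the cell divides iff
    ``t_birth < t_death``.
    """

    lambda1: float
    t_birth: float
    t_death: float | None

    @property
    def divides(self) -> bool:
        return self.t_death is None or self.t_birth < self.t_death


def draw_division_event(state, params: SimulationParams, rng) -> DivisionEvent:
    """Draw exponential waiting times to birth (rate lambda_1) and, when a
    death rate is set, to death (rate mu) for one cell."""
    lam = compute_birth_rate(state, params)
    t_b = float(rng.exponential(1.0 / lam))
    t_d = (float(rng.exponential(1.0 / params.death_rate))
           if params.death_rate > 0 else None)
    return DivisionEvent(lambda1=lam, t_birth=t_b, t_death=t_d)


@dataclass
class PopulationSummary:
    """Population-level co-assortment statistics over leaf copy states."""

    co_occurrence: float
    correlation: float
    correlation_defined: bool
    m: int
    transform: str
    pure: float
    mix: float
    free: float
    mean_cn: np.ndarray
    n_cells: int


class LineageTree:
    """Rooted binary lineage reconstructed from the simulation event log.

    Nodes are cell ids; an edge ends at the division (or the stop time for
    surviving leaves).  Dead lineages are excluded from the Newick export by
    default.
    """

    def __init__(self, n_founders, founder_states, t0, final_time,
                 leaf_ids, leaf_states, events: pd.DataFrame):
        self.parent: dict[int, int] = {}
        self.children: dict[int, tuple[int, int]] = {}
        self.birth_time: dict[int, float] = {i: t0 for i in range(n_founders)}
        self.end_time: dict[int, float] = {}
        self.dead: set[int] = set()
        self.final_time = final_time
        self.founders = list(range(n_founders))
        self.founder_states = founder_states

        for row in events.itertuples(index=False):
            if row.type == 0:
                p, d1, d2 = int(row.parent), int(row.daughter1), int(row.daughter2)
                self.children[p] = (d1, d2)
                self.parent[d1] = p
                self.parent[d2] = p
                self.birth_time[d1] = row.time
                self.birth_time[d2] = row.time
                self.end_time[p] = row.time
            else:
                self.dead.add(int(row.parent))
                self.end_time[int(row.parent)] = row.time

        self.leaf_ids = [int(i) for i in leaf_ids]
        self.leaf_states = {int(i): np.asarray(s, dtype=np.int64)
                            for i, s in zip(leaf_ids, leaf_states)}
        for i in self.leaf_ids:
            self.end_time[i] = final_time

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def edge_length(self, node: int) -> float:
        return self.end_time[node] - self.birth_time[node]

    def to_newick(self, include_dead: bool = False) -> str:
        """Newick string with leaf copy states as node comments."""
        if len(self.founders) != 1:
            raise ValueError("Newick export requires a single founder")
        alive = set(self.leaf_ids)

        def survives(node) -> bool:
            if node in alive:
                return True
            ch = self.children.get(node)
            if ch is None:
                return False
            return survives(ch[0]) or survives(ch[1])

        def render(node, extra_len=0.0):
            length = self.edge_length(node) + extra_len
            ch = self.children.get(node)
            if ch is not None and not include_dead:
                kept = [c for c in ch if survives(c)]
            elif ch is not None:
                kept = list(ch)
            else:
                kept = []
            if not kept:  # leaf (alive, or dead when included)
                state = self.leaf_states.get(node)
                comment = ""
                if state is not None:
                    comment = f"[&k1={int(state[0])},k2={int(state[1])}]"
                elif node in self.dead:
                    comment = "[&dead]"
                return f"c{node}{comment}:{length:.6g}"
            if len(kept) == 1:  # suppress unary node from pruning
                return render(kept[0], extra_len=length)
            inner = ",".join(render(c) for c in kept)
            return f"({inner}):{length:.6g}"

        root = self.founders[0]
        ch = self.children.get(root)
        if ch is None:
            return render(root) + ";"
        kept = [c for c in ch if include_dead or survives(c)]
        if len(kept) == 1:
            return render(kept[0], extra_len=self.edge_length(root)) + ";"
        inner = ",".join(render(c) for c in kept)
        return f"({inner}):{self.edge_length(root):.6g};"


@dataclass
class PopulationResult:
    """Outcome of :func:`simulate_population`.

    ``leaf_copies`` is an ``(n_cells, 2)`` integer array of per-cell copy
    numbers at the stop.  ``extinct`` marks populations that died out before
    any stop condition (an explicit result, not an exception).
    """

    leaf_copies: np.ndarray
    leaf_ids: np.ndarray
    final_time: float
    extinct: bool
    status: int
    params: SimulationParams
    events: pd.DataFrame | None = None
    tree: LineageTree | None = None

    @property
    def n_cells(self) -> int:
        return self.leaf_copies.shape[0]

    def leaves_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.leaf_ids,
            "k1": self.leaf_copies[:, 0],
            "k2": self.leaf_copies[:, 1],
        })

    def popsize_frame(self) -> pd.DataFrame:
        if self.events is None:
            raise ValueError("simulate with record_events=True for a size trace")
        return self.events[["time", "n_cells"]].copy()


def _run_kernel(params: SimulationParams, seed: int, record: int,
                init_k1: np.ndarray, init_k2: np.ndarray, t0: float,
                max_cells: int | None):
    stop = params.stop
    target_cells = stop.target_cells if stop.target_cells is not None else -1
    target_time = stop.target_time if stop.target_time is not None else np.inf

    if max_cells is None:
        if target_cells > 0:
            max_cells = target_cells + 1
        else:
            max_cells = 2_000_000
    max_cells = max(max_cells, init_k1.shape[0] + 2)

    # anchoring on species 2 is run by swapping the species for the kernel
    swap = params.coseg.anchor_species == 1
    if swap:
        init_k1, init_k2 = init_k2, init_k1
        s_mp, s_pm = params.s_plus_minus, params.s_minus_plus
    else:
        s_mp, s_pm = params.s_minus_plus, params.s_plus_minus

    max_events = 4 * max_cells + 10_000 if record > 0 else 1
    while True:
        out = _kernels.population_kernel(
            seed & 0x7FFFFFFF,
            np.ascontiguousarray(init_k1, dtype=np.int64),
            np.ascontiguousarray(init_k2, dtype=np.int64),
            float(t0),
            params.s_minus_minus, s_mp, s_pm, params.s_plus_plus,
            params.lambda_base, params.death_rate,
            params.coseg.gamma, params.coseg.coupled_fraction,
            _MODEL_CODES[params.coseg.model],
            target_cells, target_time, max_cells, record, max_events)
        if out[0] != _kernels.STATUS_EVENT_OVERFLOW:
            break
        max_events *= 4

    (status, t, k1, k2, ids, n_ev,
     ev_time, ev_type, ev_n, ev_sum1, ev_sum2,
     ev_parent, ev_d1, ev_d2, ev_d1k1, ev_d1k2, ev_d2k1, ev_d2k2) = out

    if status == _kernels.STATUS_CAPACITY:
        raise RuntimeError(
            f"population exceeded the cell capacity ({max_cells}); "
            "pass a larger max_cells for time-limited simulations")

    if swap:
        k1, k2 = k2, k1
        ev_sum1, ev_sum2 = ev_sum2, ev_sum1

    events = None
    if record > 0:
        cols = {
            "time": ev_time[:n_ev],
            "type": ev_type[:n_ev].astype(np.int64),
            "n_cells": ev_n[:n_ev],
            "mean_cn1": ev_sum1[:n_ev] / np.maximum(ev_n[:n_ev], 1),
            "mean_cn2": ev_sum2[:n_ev] / np.maximum(ev_n[:n_ev], 1),
        }
        if record == _kernels.REC_FULL:
            if swap:
                ev_d1k1, ev_d1k2 = ev_d1k2, ev_d1k1
                ev_d2k1, ev_d2k2 = ev_d2k2, ev_d2k1
            cols.update({
                "parent": ev_parent[:n_ev], "daughter1": ev_d1[:n_ev],
                "daughter2": ev_d2[:n_ev],
                "d1_k1": ev_d1k1[:n_ev], "d1_k2": ev_d1k2[:n_ev],
                "d2_k1": ev_d2k1[:n_ev], "d2_k2": ev_d2k2[:n_ev],
            })
        events = pd.DataFrame(cols)

    leaf_copies = np.stack([k1, k2], axis=1) if k1.shape[0] else np.zeros((0, 2), np.int64)
    return status, t, leaf_copies, ids, events


def simulate_population(params: SimulationParams, seed: int | None = None,
                        record_events: bool = False, keep_tree: bool | None = None,
                        max_cells: int | None = None) -> PopulationResult:
    """Simulate one population from a founder carrying ``params.k_init``.

    Fully reproducible from ``seed`` (default ``params.seed``); the leaf
    states do not depend on whether events or the tree are recorded.
    """
    seed = params.seed if seed is None else seed
    # validate birth rates for every reachable class
    for s in (params.s_minus_minus, params.s_minus_plus,
              params.s_plus_minus, params.s_plus_plus):
        if params.lambda_base * (1.0 + s) <= 0:
            raise ValueError("all class birth rates must be positive")

    if keep_tree is None:
        tc = params.stop.target_cells
        keep_tree = tc is not None and tc <= 10_000
    if keep_tree:
        tc = params.stop.target_cells
        if tc is not None and tc > TREE_LEAF_CAP:
            raise ValueError(f"lineage retention refused above {TREE_LEAF_CAP} leaves")

    record = (_kernels.REC_FULL if keep_tree
              else _kernels.REC_TRAJ if record_events else _kernels.REC_NONE)

    init_k1 = np.array([params.k_init[0]], dtype=np.int64)
    init_k2 = np.array([params.k_init[1]], dtype=np.int64)
    kseed = child_seed(seed, "population")
    status, t, leaf_copies, ids, events = _run_kernel(
        params, kseed, record, init_k1, init_k2, 0.0, max_cells)

    tree = None
    if keep_tree:
        founder = np.array(params.k_init, dtype=np.int64)
        tree = LineageTree(1, founder[None, :], 0.0, t, ids, leaf_copies, events)

    return PopulationResult(
        leaf_copies=leaf_copies, leaf_ids=ids, final_time=t,
        extinct=status == _kernels.STATUS_EXTINCT, status=status,
        params=params, events=events if record_events or keep_tree else None,
        tree=tree)


def simulate_leaf_copies(params: SimulationParams, seed: int | None = None) -> tuple[np.ndarray, bool]:
    """Fast path returning only ``(leaf_copies, extinct)``; used by ABC."""
    seed = params.seed if seed is None else seed
    init_k1 = np.array([params.k_init[0]], dtype=np.int64)
    init_k2 = np.array([params.k_init[1]], dtype=np.int64)
    kseed = child_seed(seed, "population")
    status, _, leaf_copies, _, _ = _run_kernel(
        params, kseed, _kernels.REC_NONE, init_k1, init_k2, 0.0, None)
    return leaf_copies, status == _kernels.STATUS_EXTINCT


def _as_leaf_array(leaves) -> np.ndarray:
    if isinstance(leaves, PopulationResult):
        leaves = leaves.leaf_copies
    arr = np.asarray(leaves)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("leaves must be an (n, 2) array of copy numbers")
    if arr.shape[0] == 0:
        raise ValueError("empty leaf set")
    return arr


def subpopulation_fractions(leaves) -> tuple[float, float, float]:
    """Fractions of (pure, mix, free) cells: exactly one / both / neither
    species present."""
    arr = _as_leaf_array(leaves)
    has1 = arr[:, 0] > 0
    has2 = arr[:, 1] > 0
    mix = float(np.mean(has1 & has2))
    free = float(np.mean(~has1 & ~has2))
    pure = 1.0 - mix - free
    return pure, mix, free


def summarize_population(leaves, m: int = 1, transform: str = "raw") -> PopulationSummary:
    """Co-occurrence ``C`` and copy-number correlation ``rho`` over leaves.

    ``C`` is the fraction of cells with both species strictly above the
    threshold ``m``.  ``rho`` is the Pearson correlation of per-cell copy
    numbers, computed on ``log(1 + k)`` when ``transform='log'``; it is
    flagged undefined when either species is constant across cells.
    """
    if m < 0:
        raise ValueError("threshold m must be non-negative")
    if transform not in ("raw", "log"):
        raise ValueError("transform must be 'raw' or 'log'")
    arr = _as_leaf_array(leaves)
    c = float(np.mean((arr[:, 0] > m) & (arr[:, 1] > m)))
    x = arr.astype(np.float64)
    if transform == "log":
        x = np.log1p(x)
    defined = (arr.shape[0] >= 2
               and np.ptp(x[:, 0]) > 0 and np.ptp(x[:, 1]) > 0)
    if defined:
        rho = float(np.corrcoef(x[:, 0], x[:, 1])[0, 1])
    else:
        rho = float("nan")
    pure, mix, free = subpopulation_fractions(arr)
    return PopulationSummary(
        co_occurrence=c, correlation=rho, correlation_defined=defined,
        m=m, transform=transform, pure=pure, mix=mix, free=free,
        mean_cn=arr.mean(axis=0), n_cells=arr.shape[0])
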