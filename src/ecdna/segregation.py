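"""Mitotic segregation rules for two co-existing ecDNA species.

ecDNAs lack centromeres, so at cell division the replicated copies of each
species are partitioned between the two daughter cells at random.  This
module implements three partition rules for a parent carrying copy numbers
``(N1, N2)`` (which double to ``(2*N1, 2*N2)`` before the split):

``element_level``
    Species 1 (the *anchor*) splits as ``Binomial(2*N1, 1/2)``.  A
    deterministic share of species 2 proportional to the co-segregation
    coefficient ``gamma`` follows the anchor's split ratio into each
    daughter; the leftover copies split binomially.  ``gamma = 0`` is fully
    independent segregation, ``gamma = 1`` fully proportional.

``cell_level``
    Both species split independently as ``Binomial(2*N, 1/2)``; with
    probability ``gamma`` the larger half of species 2 is placed in the
    daughter that received the larger half of species 1 (extreme
    copy-number correlation), otherwise in the opposite daughter.
    ``gamma = 0.5`` reproduces independent random segregation.

``fraction_coupled``
    A fraction ``phi`` of each species' doubled copies is distributed at one
    shared random ratio drawn once per division; the remaining copies split
    independently.  ``phi`` equal to an observed fraction of covalently
    fused molecules gives the fusion-only null used for daughter-pair
    statistics.

All rules conserve copies exactly (daughter totals sum to ``2*N_j``) and are
exchangeable in the daughters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .rng import as_generator

__all__ = [
    "CopyState",
    "CosegParams",
    "DivisionOutcome",
    "element_coupled_parts",
    "segregate",
    "segregate_element_level",
    "segregate_cell_level",
    "segregate_fraction_coupled",
    "sample_divisions",
    "divisions_to_frame",
]

MODELS = ("element_level", "cell_level", "fraction_coupled")

# guard against 3.9999999... when the coupled share is an exact integer
_FLOOR_EPS = 1e-9


@dataclass
class CopyState:
    """Per-cell integer copy numbers, one entry per ecDNA species."""

    copies: np.ndarray

    def __post_init__(self):
        self.copies = np.asarray(self.copies, dtype=np.int64)
        if self.copies.ndim != 1:
            raise ValueError("copies must be a 1-D vector")
        if np.any(self.copies < 0):
            raise ValueError("copy numbers must be non-negative")

    @property
    def n_species(self) -> int:
        return self.copies.shape[0]

    def __getitem__(self, j: int) -> int:
        return int(self.copies[j])


@dataclass
class CosegParams:
    """Parameters of a segregation rule.

    gamma : co-segregation coefficient in [0, 1] (element/cell level).
    model : one of ``element_level``, ``cell_level``, ``fraction_coupled``.
    coupled_fraction : shared-ratio fraction ``phi`` in [0, 1]
        (fraction_coupled only).
    anchor_species : index of the species whose split conditions the other.
    """

    gamma: float = 0.0
    model: str = "element_level"
    coupled_fraction: float = 0.0
    anchor_species: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown segregation model {self.model!r}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ValueError("coupled_fraction must lie in [0, 1]")
        if self.anchor_species not in (0, 1):
            raise ValueError("anchor_species must be 0 or 1")


@dataclass
class DivisionOutcome:
    """Result of one division.

    ``coupled_part[i]`` / ``random_part[i]`` decompose the copies of the
    non-anchor species received by daughter ``i+1`` into the share that
    followed the anchor (or the shared ratio) and the share that segregated
    independently.  Rules without a coupled component leave them at zero.
    """

    daughter1: CopyState
    daughter2: CopyState
    coupled_part: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))
    random_part: np.ndarray = field(default_factory=lambda: np.zeros(2, dtype=np.int64))


def _require_two_species(parent: CopyState):
    if parent.n_species != 2:
        raise ValueError("segregation rules are defined for exactly 2 species")


def element_coupled_parts(n_anchor: int, n_other: int, gamma: float,
                          anchor_d1: int) -> tuple[int, int]:
    """Deterministic coupled copies of the non-anchor species per daughter.

    For a parent with ``n_anchor`` anchor copies whose doubled anchor pool
    split ``anchor_d1`` / ``2*n_anchor - anchor_d1``, the coupled share of
    the other species in daughter ``i`` is
    ``floor(gamma * 2*n_other * anchor_di / (2*n_anchor))``.  When the
    anchor is absent there is no signal to couple to and both parts are 0.
    """
    if n_anchor == 0:
        return 0, 0
    tot_a = 2 * n_anchor
    c1 = int(math.floor(gamma * 2 * n_other * anchor_d1 / tot_a + _FLOOR_EPS))
    c2 = int(math.floor(gamma * 2 * n_other * (tot_a - anchor_d1) / tot_a + _FLOOR_EPS))
    return c1, c2


def segregate_element_level(parent: CopyState, params: CosegParams, rng) -> DivisionOutcome:
    """One division under the element-level (proportional-share) rule."""
    _require_two_species(parent)
    rng = as_generator(rng)
    a, b = params.anchor_species, 1 - params.anchor_species
    Na, Nb = parent[a], parent[b]

    na1 = int(rng.binomial(2 * Na, 0.5)) if Na > 0 else 0
    c1, c2 = element_coupled_parts(Na, Nb, params.gamma, na1)
    rem = 2 * Nb - c1 - c2
    r1 = int(rng.binomial(rem, 0.5)) if rem > 0 else 0
    nb1 = c1 + r1

    d1 = np.zeros(2, dtype=np.int64)
    d2 = np.zeros(2, dtype=np.int64)
    d1[a], d1[b] = na1, nb1
    d2[a], d2[b] = 2 * Na - na1, 2 * Nb - nb1
    coupled = np.array([c1, c2], dtype=np.int64)
    rand_part = np.array([r1, rem - r1], dtype=np.int64)
    return DivisionOutcome(CopyState(d1), CopyState(d2), coupled, rand_part)


def segregate_cell_level(parent: CopyState, params: CosegParams, rng) -> DivisionOutcome:
    """One division under the cell-level (half-pairing) rule."""
    _require_two_species(parent)
    rng = as_generator(rng)
    N1, N2 = parent[0], parent[1]
    b1 = int(rng.binomial(2 * N1, 0.5)) if N1 > 0 else 0
    b2 = int(rng.binomial(2 * N2, 0.5)) if N2 > 0 else 0
    hi1, lo1 = max(b1, 2 * N1 - b1), min(b1, 2 * N1 - b1)
    hi2, lo2 = max(b2, 2 * N2 - b2), min(b2, 2 * N2 - b2)
    if rng.random() < params.gamma:
        dA = (hi1, hi2)
        dB = (lo1, lo2)
    else:
        dA = (hi1, lo2)
        dB = (lo1, hi2)
    if rng.random() < 0.5:  # exchangeable daughter labelling
        dA, dB = dB, dA
    return DivisionOutcome(
        CopyState(np.array(dA, dtype=np.int64)),
        CopyState(np.array(dB, dtype=np.int64)),
    )


def _coupled_counts(copies: np.ndarray, phi: float) -> np.ndarray:
    return np.rint(phi * 2 * copies).astype(np.int64)


def segregate_fraction_coupled(parent: CopyState, params: CosegParams, rng) -> DivisionOutcome:
    """One division under the shared-ratio (fraction-coupled) rule."""
    rng = as_generator(rng)
    phi = params.coupled_fraction
    copies = parent.copies
    coupled = _coupled_counts(copies, phi)
    a = params.anchor_species if parent.n_species > params.anchor_species else 0
    ca = int(coupled[a])
    if ca > 0:
        xa = int(rng.binomial(ca, 0.5))
        ratio = xa / ca
    else:
        # no anchor copies in the coupled pool: uninformative shared ratio
        xa = 0
        ratio = float(rng.random())
    c_d1 = np.rint(ratio * coupled).astype(np.int64)
    c_d1[a] = xa
    rem = 2 * copies - coupled
    r_d1 = np.asarray(rng.binomial(rem, 0.5), dtype=np.int64)
    d1 = c_d1 + r_d1
    d2 = 2 * copies - d1
    if rng.random() < 0.5:  # exchangeable daughter labelling
        d1, d2 = d2, d1
        c_d1 = coupled - c_d1
        r_d1 = rem - r_d1
    b = 1 - a if parent.n_species == 2 else a
    coupled_by_daughter = np.array([c_d1[b], coupled[b] - c_d1[b]], dtype=np.int64)
    random_by_daughter = np.array([r_d1[b], rem[b] - r_d1[b]], dtype=np.int64)
    return DivisionOutcome(CopyState(d1), CopyState(d2),
                           coupled_by_daughter, random_by_daughter)


_DISPATCH = {
    "element_level": segregate_element_level,
    "cell_level": segregate_cell_level,
    "fraction_coupled": segregate_fraction_coupled,
}


def segregate(parent: CopyState, params: CosegParams, rng) -> DivisionOutcome:
    """Dispatch a single division to the rule named in ``params.model``."""
    return _DISPATCH[params.model](parent, params, rng)


def sample_divisions(parent: CopyState, params: CosegParams, n: int, rng):
    """Vectorized replicate divisions of the same parent.

    Returns a pair of ``(n, n_species)`` integer arrays ``(d1, d2)`` with the
    copies received by each daughter in each of ``n`` independent divisions.
    Used for the large Monte Carlo checks (marginal distributions,
    daughter-pair calibration, fusion nulls) where a Python loop over
    :func:`segregate` would dominate runtime.
    """
    rng = as_generator(rng)
    n = int(n)
    if n < 0:
        raise ValueError("n must be non-negative")
    model = params.model
    copies = parent.copies

    if model == "fraction_coupled":
        phi = params.coupled_fraction
        coupled = _coupled_counts(copies, phi)
        a = params.anchor_species
        ca = int(coupled[a])
        if ca > 0:
            xa = rng.binomial(ca, 0.5, size=n)
            ratio = xa / ca
        else:
            xa = np.zeros(n, dtype=np.int64)
            ratio = rng.random(n)
        c_d1 = np.rint(ratio[:, None] * coupled[None, :]).astype(np.int64)
        c_d1[:, a] = xa
        rem = 2 * copies - coupled
        r_d1 = rng.binomial(rem[None, :], 0.5, size=(n, copies.shape[0]))
        d1 = c_d1 + r_d1
        d2 = 2 * copies - d1
        swap = rng.random(n) < 0.5
        d1s = np.where(swap[:, None], d2, d1)
        d2s = np.where(swap[:, None], d1, d2)
        return d1s, d2s

    _require_two_species(parent)
    if model == "element_level":
        a, b = params.anchor_species, 1 - params.anchor_species
        Na, Nb = int(copies[a]), int(copies[b])
        na1 = rng.binomial(2 * Na, 0.5, size=n) if Na > 0 else np.zeros(n, dtype=np.int64)
        if Na > 0:
            scale = params.gamma * 2 * Nb / (2 * Na)
            c1 = np.floor(scale * na1 + _FLOOR_EPS).astype(np.int64)
            c2 = np.floor(scale * (2 * Na - na1) + _FLOOR_EPS).astype(np.int64)
        else:
            c1 = np.zeros(n, dtype=np.int64)
            c2 = np.zeros(n, dtype=np.int64)
        rem = 2 * Nb - c1 - c2
        r1 = rng.binomial(rem, 0.5)
        nb1 = c1 + r1
        d1 = np.empty((n, 2), dtype=np.int64)
        d2 = np.empty((n, 2), dtype=np.int64)
        d1[:, a], d1[:, b] = na1, nb1
        d2[:, a], d2[:, b] = 2 * Na - na1, 2 * Nb - nb1
        return d1, d2

    # cell_level
    N1, N2 = int(copies[0]), int(copies[1])
    b1 = rng.binomial(2 * N1, 0.5, size=n) if N1 > 0 else np.zeros(n, dtype=np.int64)
    b2 = rng.binomial(2 * N2, 0.5, size=n) if N2 > 0 else np.zeros(n, dtype=np.int64)
    hi1 = np.maximum(b1, 2 * N1 - b1)
    lo1 = 2 * N1 - hi1
    hi2 = np.maximum(b2, 2 * N2 - b2)
    lo2 = 2 * N2 - hi2
    same = rng.random(n) < params.gamma
    sA2 = np.where(same, hi2, lo2)
    sB2 = np.where(same, lo2, hi2)
    swap = rng.random(n) < 0.5
    d1 = np.stack([np.where(swap, lo1, hi1), np.where(swap, sB2, sA2)], axis=1)
    d2 = np.stack([np.where(swap, hi1, lo1), np.where(swap, sA2, sB2)], axis=1)
    return d1, d2


def divisions_to_frame(outcomes: list[DivisionOutcome]):
    """Tidy per-species division trace (exportable as TSV)."""
    import pandas as pd

    rows = []
    for i, out in enumerate(outcomes):
        for j in range(out.daughter1.n_species):
            rows.append({
                "division_id": i,
                "species": j,
                "n_daughter1": out.daughter1[j],
                "n_daughter2": out.daughter2[j],
                "coupled_part1": int(out.coupled_part[0]),
                "coupled_part2": int(out.coupled_part[1]),
            })
    return pd.DataFrame(rows)
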