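"""Statistics on daughter-cell pairs at mitosis.

Imaging of dividing cells (FISH signal per species in each daughter of a
pair) yields, for every pair and species ``j``, the inherited proportion
``p_j = d1_j / (d1_j + d2_j)``.  Correlated proportions across species
indicate co-segregation.  This module computes the co-segregation
correlation, compares correlations between conditions with Fisher's z
transformation, builds the covalent-fusion null (the correlation expected
if only the observed fraction of fused molecules co-segregated perfectly,
everything else splitting independently), and calibrates the expected
correlation as a function of the coupled fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rng import substream
from .segregation import CopyState, CosegParams, sample_divisions

__all__ = [
    "PairSet",
    "read_pairs_tsv",
    "coseg_correlation",
    "fisher_z_compare",
    "FusionNullResult",
    "fusion_null",
    "coseg_calibration_curve",
    "PairCorrelation",
]


@dataclass
class PairCorrelation:
    r: float
    p: float
    n: int
    defined: bool
    n_excluded: int = 0


class PairSet:
    """A set of daughter-pair observations for one condition.

    Stored wide: one row per pair with the per-species signal in each
    daughter (``s1_d1, s1_d2, s2_d1, s2_d2``), the observed fraction of
    fused molecules, and a condition label.  Signals may be FISH integrated
    intensity or pixel area; the two are treated interchangeably and never
    converted.
    """

    COLUMNS = ["pair_id", "s1_d1", "s1_d2", "s2_d1", "s2_d2",
               "fusion_fraction", "condition"]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"pair table missing columns {sorted(missing)}")
        if (frame[["s1_d1", "s1_d2", "s2_d1", "s2_d2"]] < 0).any().any():
            raise ValueError("signals must be non-negative")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def condition(self) -> str:
        return self.frame["condition"].iloc[0] if len(self.frame) else ""

    def proportions(self, daughter: int = 1):
        """(p1, p2, valid) arrays: per-pair inherited proportion of each
        species in the chosen daughter; pairs with zero total signal for
        either species are flagged invalid (QC-excluded)."""
        f = self.frame
        tot1 = (f["s1_d1"] + f["s1_d2"]).to_numpy(dtype=float)
        tot2 = (f["s2_d1"] + f["s2_d2"]).to_numpy(dtype=float)
        valid = (tot1 > 0) & (tot2 > 0)
        col1 = "s1_d1" if daughter == 1 else "s1_d2"
        col2 = "s2_d1" if daughter == 1 else "s2_d2"
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = np.where(valid, f[col1].to_numpy(dtype=float) / tot1, np.nan)
            p2 = np.where(valid, f[col2].to_numpy(dtype=float) / tot2, np.nan)
        return p1, p2, valid

    def to_tidy(self) -> pd.DataFrame:
        """Long format (pair_id, species, signal_d1, signal_d2, ...) as used
        in TSV interchange."""
        rows = []
        for _, r in self.frame.iterrows():
            for j in (1, 2):
                rows.append({
                    "pair_id": r["pair_id"], "species": j,
                    "signal_d1": r[f"s{j}_d1"], "signal_d2": r[f"s{j}_d2"],
                    "fusion_fraction": r["fusion_fraction"],
                    "condition": r["condition"]})
        return pd.DataFrame(rows)

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame) -> "PairSet":
        wide = {}
        for _, r in tidy.iterrows():
            rec = wide.setdefault(r["pair_id"], {
                "pair_id": r["pair_id"],
                "fusion_fraction": r["fusion_fraction"],
                "condition": r["condition"]})
            j = int(r["species"])
            rec[f"s{j}_d1"] = r["signal_d1"]
            rec[f"s{j}_d2"] = r["signal_d2"]
        return cls(pd.DataFrame(list(wide.values())))


def read_pairs_tsv(path) -> PairSet:
    return PairSet.from_tidy(pd.read_csv(path, sep="\t"))


def coseg_correlation(pairs: PairSet, daughter: int = 1) -> PairCorrelation:
    """Pearson correlation between the two species' inherited proportions.

    Invariant (up to sign conventions, |R|) to the choice of daughter since
    the proportions in daughter 2 are one minus those in daughter 1.
    """
    p1, p2, valid = pairs.proportions(daughter)
    p1, p2 = p1[valid], p2[valid]
    n = p1.shape[0]
    n_excl = int((~valid).sum())
    if n < 3 or np.ptp(p1) == 0 or np.ptp(p2) == 0:
        return PairCorrelation(float("nan"), float("nan"), n, False, n_excl)
    r, p = stats.pearsonr(p1, p2)
    return PairCorrelation(float(r), float(p), n, True, n_excl)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int,
                     sided: str = "two") -> tuple[float, float]:
    """Compare two independent Pearson correlations via Fisher's z.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    standard-normal reference; one-sided tests the alternative ``r1 > r2``.
    """
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the z transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    if sided == "one":
        p = float(stats.norm.sf(z))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


@dataclass
class FusionNullResult:
    """Fusion-only null distribution of the daughter-pair correlation."""

    observed_r: float
    null_r: np.ndarray
    z: float
    p: float
    n_pairs: int

    def percentile_of_observed(self) -> float:
        return float(np.mean(self.null_r < self.observed_r) * 100.0)


def _pair_pseudo_copies(pairs: PairSet, total_copies: int):
    """Integer pseudo-copy numbers per pair and species, scaling each
    pair's total signal to ``total_copies`` molecules (FISH intensity is
    not calibrated to molecule counts; this is a documented approximation)."""
    f = pairs.frame
    tot1 = (f["s1_d1"] + f["s1_d2"]).to_numpy(dtype=float)
    tot2 = (f["s2_d1"] + f["s2_d2"]).to_numpy(dtype=float)
    valid = (tot1 > 0) & (tot2 > 0)
    share1 = tot1[valid] / (tot1[valid] + tot2[valid])
    n1 = np.maximum(1, np.rint(total_copies * share1)).astype(np.int64)
    n2 = np.maximum(1, total_copies - n1)
    return n1, n2, valid


def fusion_null(pairs: PairSet, n_events: int = 20, total_copies: int = 200,
                seed: int = 0) -> FusionNullResult:
    """Null distribution of R from covalent fusions alone.

    For each observed pair, ``n_events`` divisions are simulated under the
    fraction-coupled rule with the coupled fraction set to that pair's
    observed fused-molecule fraction (fused copies perfectly co-segregate,
    the remainder splits independently).  Simulated event ``e`` of every
    pair forms null replicate dataset ``e``, giving ``n_events`` null
    correlations.  The observed correlation is compared with the null mean
    by Fisher's z (two-sided).
    """
    f = pairs.frame
    if f["fusion_fraction"].isna().any():
        raise ValueError("every pair needs a fusion_fraction")
    obs = coseg_correlation(pairs)
    n1s, n2s, valid = _pair_pseudo_copies(pairs, total_copies)
    fus = f["fusion_fraction"].to_numpy(dtype=float)[valid]
    rng = substream(seed, "fusion-null")

    n_pairs = n1s.shape[0]
    p1 = np.empty((n_events, n_pairs))
    p2 = np.empty((n_events, n_pairs))
    for k in range(n_pairs):
        params = CosegParams(model="fraction_coupled",
                             coupled_fraction=float(fus[k]))
        parent = CopyState(np.array([n1s[k], n2s[k]]))
        d1, _ = sample_divisions(parent, params, n_events, rng)
        p1[:, k] = d1[:, 0] / (2.0 * n1s[k])
        p2[:, k] = d1[:, 1] / (2.0 * n2s[k])

    null_r = np.empty(n_events)
    for e in range(n_events):
        if np.ptp(p1[e]) == 0 or np.ptp(p2[e]) == 0:
            null_r[e] = 0.0
        else:
            null_r[e] = np.corrcoef(p1[e], p2[e])[0, 1]

    # z of observed R against the null mean; the null mean's own Monte
    # Carlo uncertainty contributes the 1/n_events term
    r_null = float(np.tanh(np.mean(np.arctanh(np.clip(null_r, -0.999999, 0.999999)))))
    se = math.sqrt((1.0 + 1.0 / n_events) / (obs.n - 3))
    z = (math.atanh(obs.r) - math.atanh(r_null)) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return FusionNullResult(observed_r=obs.r, null_r=null_r, z=z, p=p,
                            n_pairs=n_pairs)


def coseg_calibration_curve(copies=(100, 100), phis=(0.0, 0.25, 0.5, 0.75, 1.0),
                            n_pairs: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Expected daughter-pair correlation as a function of the coupled
    fraction ``phi``; maps an observed R onto an implied co-segregation
    level (the relationship is close to linear for high copy numbers)."""
    rng = substream(seed, "calibration")
    parent = CopyState(np.asarray(copies, dtype=np.int64))
    rows = []
    for phi in phis:
        params = CosegParams(model="fraction_coupled", coupled_fraction=float(phi))
        d1, _ = sample_divisions(parent, params, n_pairs, rng)
        p1 = d1[:, 0] / (2.0 * parent[0])
        p2 = d1[:, 1] / (2.0 * parent[1])
        if np.ptp(p1) == 0 or np.ptp(p2) == 0:
            r = 1.0 if phi == 1.0 else 0.0
        else:
            r = float(np.corrcoef(p1, p2)[0, 1])
        rows.append({"phi": float(phi), "expected_r": r})
    return pd.DataFrame(rows)
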