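"""Single-cell copy-number calling from windowed insertion counts.

Follows the background-normalization approach used for scATAC-seq data:
insertion counts are tallied in large sliding windows (3 Mb, 1 Mb step),
each window's insertions-per-bp rate is compared per cell against the mean
rate of its 100 nearest non-overlapping windows in GC content (cancelling
accessibility/sequence bias), and copy number is obtained on a diploid
baseline as

    CN = 2 * 2 ** log2(FC)

where FC is the fold change of the window rate over its GC-matched
neighbour mean.  Gene-level copy numbers average the windows overlapping
the gene.  Focal amplifications are classified by the joint rule
``mean CN >= 4 and variance/mean >= 2.5``: ecDNAs segregate randomly at
mitosis and therefore show inflated cell-to-cell variance, unlike
chromosomal (HSR) amplifications of comparable mean copy number.

Coordinates are BED-style 0-based half-open throughout; the genome build is
caller-supplied metadata and never assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "sliding_windows",
    "apply_blacklist",
    "gc_matched_neighbors",
    "CopyNumberResult",
    "compute_copy_number",
    "gene_copy_number",
    "AmpliconCall",
    "classify_amplicon",
    "amplicon_correlation",
    "read_window_counts",
    "write_window_counts",
]

WINDOW_SIZE = 3_000_000
WINDOW_STEP = 1_000_000


def sliding_windows(chrom_sizes: dict[str, int], window: int = WINDOW_SIZE,
                    step: int = WINDOW_STEP) -> pd.DataFrame:
    """Sliding genomic windows (columns chrom/start/end); only full-width
    windows are emitted so all rates share the same denominator."""
    rows = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size - window + 1, step):
            rows.append((chrom, start, start + window))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _overlaps(chrom_a, s_a, e_a, chrom_b, s_b, e_b):
    return (chrom_a == chrom_b) & (s_a < e_b) & (s_b < e_a)


def apply_blacklist(windows: pd.DataFrame, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Flag windows overlapping any blacklist interval by >= 1 bp."""
    windows = windows.copy()
    flagged = np.zeros(len(windows), dtype=bool)
    for _, bl in blacklist.iterrows():
        flagged |= ((windows["chrom"] == bl["chrom"])
                    & (windows["start"] < bl["end"])
                    & (bl["start"] < windows["end"])).to_numpy()
    windows["blacklisted"] = flagged
    return windows


def gc_matched_neighbors(windows: pd.DataFrame, n_neighbours: int = 100) -> np.ndarray:
    """Index matrix of each window's GC-nearest non-overlapping windows.

    For every (non-blacklisted) window, candidate neighbours are all other
    kept windows that do not overlap it genomically (sliding windows within
    one window-width share sequence), ranked by |delta GC| with ties broken
    by genomic distance.  Returns an (n_windows, n_neighbours) int array of
    row positions into ``windows``.
    """
    if "gc" not in windows.columns:
        raise ValueError("windows need a 'gc' column")
    gc = windows["gc"].to_numpy(dtype=float)
    chrom = windows["chrom"].to_numpy()
    start = windows["start"].to_numpy(dtype=np.int64)
    end = windows["end"].to_numpy(dtype=np.int64)
    w = len(windows)
    if w <= n_neighbours:
        raise ValueError(f"need more than {n_neighbours} windows, got {w}")
    nbrs = np.empty((w, n_neighbours), dtype=np.int64)
    for i in range(w):
        overlap = (chrom == chrom[i]) & (start < end[i]) & (start[i] < end)
        cand = np.flatnonzero(~overlap)
        if cand.shape[0] < n_neighbours:
            raise ValueError("too few non-overlapping windows for neighbour matching")
        dgc = np.abs(gc[cand] - gc[i])
        dist = np.where(chrom[cand] == chrom[i],
                        np.abs(start[cand] - start[i]), np.iinfo(np.int64).max)
        order = np.lexsort((dist, dgc))
        nbrs[i] = cand[order[:n_neighbours]]
    return nbrs


@dataclass
class CopyNumberResult:
    """Per-cell, per-window copy numbers with the underlying fold changes."""

    cn: np.ndarray          # (n_cells, n_windows)
    log2fc: np.ndarray
    windows: pd.DataFrame   # the (kept) windows the columns refer to
    cell_ids: np.ndarray
    neighbors: np.ndarray
    low_coverage_cells: np.ndarray  # bool mask: pseudocount policy applied

    def frame(self) -> pd.DataFrame:
        cols = [f"{c}:{s}-{e}" for c, s, e in
                zip(self.windows["chrom"], self.windows["start"], self.windows["end"])]
        return pd.DataFrame(self.cn, index=self.cell_ids, columns=cols)


def compute_copy_number(counts, windows: pd.DataFrame,
                        n_neighbours: int = 100,
                        cell_ids=None) -> CopyNumberResult:
    """Background-normalized copy number per cell and window.

    ``counts`` is a (cells x windows) matrix of insertion counts (sparse or
    dense) aligned with ``windows`` rows.  Blacklisted windows are dropped
    before neighbour matching.  Cells in which some neighbour mean is zero
    are recomputed with a +1 insertion pseudocount per window and flagged
    ``low_coverage``.
    """
    counts = sp.csr_matrix(counts) if not sp.issparse(counts) else counts.tocsr()
    if counts.shape[1] != len(windows):
        raise ValueError("counts columns must match windows rows")
    keep = ~windows["blacklisted"].to_numpy() if "blacklisted" in windows else \
        np.ones(len(windows), dtype=bool)
    kept_windows = windows.loc[keep].reset_index(drop=True)
    counts = counts[:, np.flatnonzero(keep)]
    widths = (kept_windows["end"] - kept_windows["start"]).to_numpy(dtype=float)
    nbrs = gc_matched_neighbors(kept_windows, n_neighbours)

    # sparse averaging operator: row i holds 1/n over window i's neighbours
    w = len(kept_windows)
    rows = np.repeat(np.arange(w), n_neighbours)
    avg = sp.csr_matrix((np.full(w * n_neighbours, 1.0 / n_neighbours),
                         (rows, nbrs.ravel())), shape=(w, w))

    dense = counts.toarray().astype(np.float64)
    rates = dense / widths[None, :]
    nb_mean = (avg @ rates.T).T

    low = (nb_mean <= 0).any(axis=1)
    if low.any():
        rates_pc = (dense[low] + 1.0) / widths[None, :]
        nb_mean[low] = (avg @ rates_pc.T).T
        rates[low] = rates_pc

    with np.errstate(divide="ignore"):  # zero-count windows: log2FC=-inf, CN=0
        log2fc = np.log2(rates / nb_mean)
    cn = 2.0 * (rates / nb_mean)
    if cell_ids is None:
        cell_ids = np.array([f"cell{i}" for i in range(counts.shape[0])])
    return CopyNumberResult(cn=cn, log2fc=log2fc, windows=kept_windows,
                            cell_ids=np.asarray(cell_ids), neighbors=nbrs,
                            low_coverage_cells=low)


def gene_copy_number(cnres: CopyNumberResult, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-cell gene copy number: mean CN of windows overlapping each gene
    (any shared base, half-open arithmetic).  Genes without an overlapping
    window get NaN with a warning."""
    chrom = cnres.windows["chrom"].to_numpy()
    start = cnres.windows["start"].to_numpy()
    end = cnres.windows["end"].to_numpy()
    out = {}
    for _, g in genes.iterrows():
        sel = (chrom == g["chrom"]) & (start < g["end"]) & (g["start"] < end)
        name = g["name"]
        if not sel.any():
            warnings.warn(f"gene {name} overlaps no retained window")
            out[name] = np.full(cnres.cn.shape[0], np.nan)
        else:
            out[name] = cnres.cn[:, sel].mean(axis=1)
    return pd.DataFrame(out, index=cnres.cell_ids)


@dataclass
class AmpliconCall:
    """ecDNA-signature classification of one amplified region."""

    region: str
    mean_cn: float
    var_mean_ratio: float
    call: str  # ecDNA-like | amplified-non-ecDNA | not-amplified | indeterminate
    n_cells: int


def classify_amplicon(cn_values, region: str = "", min_cells: int = 10,
                      mean_threshold: float = 4.0,
                      vmr_threshold: float = 2.5) -> AmpliconCall:
    """Classify a per-cell CN vector by the mean / variance-mean-ratio rule
    (thresholds inclusive)."""
    v = np.asarray(cn_values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.shape[0]
    if n < min_cells:
        return AmpliconCall(region, float("nan"), float("nan"), "indeterminate", n)
    mean = float(v.mean())
    vmr = float(v.var(ddof=1) / mean) if mean > 0 else 0.0
    if mean >= mean_threshold and vmr >= vmr_threshold:
        call = "ecDNA-like"
    elif mean >= mean_threshold:
        call = "amplified-non-ecDNA"
    else:
        call = "not-amplified"
    return AmpliconCall(region, mean, vmr, call, n)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    defined: bool


def amplicon_correlation(gene_cn: pd.DataFrame, gene_a: str, gene_b: str,
                         mode: str = "all-cells-log", min_cells: int = 3,
                         amp_threshold: float = 4.0) -> CorrelationResult:
    """Pearson correlation of two genes' per-cell copy numbers.

    ``all-cells-log``: correlation of log CN over every cell (cell-line
    analysis).  ``amplified-only``: raw CN restricted to cells where both
    genes are amplified (CN >= ``amp_threshold``; tumour analysis).
    """
    if mode not in ("all-cells-log", "amplified-only"):
        raise ValueError("mode must be 'all-cells-log' or 'amplified-only'")
    a = gene_cn[gene_a].to_numpy(dtype=float)
    b = gene_cn[gene_b].to_numpy(dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if mode == "amplified-only":
        sel = (a >= amp_threshold) & (b >= amp_threshold)
        a, b = a[sel], b[sel]
    else:
        a, b = np.log(np.maximum(a, 1e-9)), np.log(np.maximum(b, 1e-9))
    n = a.shape[0]
    if n < min_cells or np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, False)
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(float(r), float(p), n, True)


def write_window_counts(outdir, counts, windows: pd.DataFrame, cell_ids):
    """Write counts as MatrixMarket + windows BED + barcodes TSV."""
    import os

    from scipy.io import mmwrite

    os.makedirs(outdir, exist_ok=True)
    mmwrite(os.path.join(outdir, "counts.mtx"), sp.coo_matrix(counts))
    cols = ["chrom", "start", "end"] + [c for c in ("gc",) if c in windows]
    windows[cols].to_csv(os.path.join(outdir, "windows.bed"),
                         sep="\t", header=False, index=False)
    pd.Series(cell_ids).to_csv(os.path.join(outdir, "barcodes.tsv"),
                               header=False, index=False)


def read_window_counts(outdir):
    """Read the (counts, windows, cell_ids) triple written by
    :func:`write_window_counts`."""
    import os

    from scipy.io import mmread

    counts = sp.csr_matrix(mmread(os.path.join(outdir, "counts.mtx")))
    bed = pd.read_csv(os.path.join(outdir, "windows.bed"), sep="\t", header=None)
    bed.columns = ["chrom", "start", "end", "gc"][: bed.shape[1]]
    cells = pd.read_csv(os.path.join(outdir, "barcodes.tsv"), header=None)[0].to_numpy()
    return counts, bed, cells
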