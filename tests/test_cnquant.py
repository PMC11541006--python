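"""Copy-number calling: the normalization formula, GC-matched neighbours,
gene aggregation, the ecDNA-signature rule and amplicon correlations."""

import numpy as np
import pandas as pd
import pytest

from ecdna.cnquant import (amplicon_correlation, apply_blacklist,
                           classify_amplicon, compute_copy_number,
                           gc_matched_neighbors, gene_copy_number,
                           read_window_counts, sliding_windows)
from ecdna.synth import (AmpliconSpec, cn_profile_fixed, cn_profile_nbinom,
                         cn_profiles_from_simulation, gen_counts_matrix)


@pytest.fixture
def flat_windows():
    return gen_counts_matrix(n_cells=2, n_windows=300, depth=1000,
                             gc_coeffs=(0.0, 0.0), seed=1).windows


def test_sliding_window_geometry():
    w = sliding_windows({"chr1": 10_000_000}, window=3_000_000, step=1_000_000)
    assert len(w) == 8
    assert (w["end"] - w["start"] == 3_000_000).all()
    assert w["start"].iloc[1] == 1_000_000


def test_blacklist_overlap_by_one_base():
    w = sliding_windows({"chr1": 10_000_000})
    bl = pd.DataFrame({"chrom": ["chr1"], "start": [2_999_999], "end": [3_000_000]})
    flagged = apply_blacklist(w, bl)
    # windows covering base 2,999,999: starts 0, 1M, 2M
    assert flagged["blacklisted"].sum() == 3


def test_neighbors_exclude_overlapping_windows(flat_windows):
    nbrs = gc_matched_neighbors(flat_windows, n_neighbours=50)
    start = flat_windows["start"].to_numpy()
    end = flat_windows["end"].to_numpy()
    i = 150
    assert i not in nbrs[i]
    for j in nbrs[i]:
        assert not (start[j] < end[i] and start[i] < end[j])


def test_unit_fold_change_gives_diploid(flat_windows):
    counts = np.full((3, 300), 10)
    res = compute_copy_number(counts, flat_windows, n_neighbours=100)
    assert np.allclose(res.cn, 2.0)
    assert np.allclose(res.log2fc, 0.0)


def test_fourfold_rate_gives_cn8(flat_windows):
    counts = np.full((3, 300), 10)
    counts[1, 42] = 40
    res = compute_copy_number(counts, flat_windows, n_neighbours=100)
    assert res.cn[1, 42] == pytest.approx(8.0)
    assert res.cn[0, 42] == pytest.approx(2.0)


def test_all_zero_cell_pseudocount_policy(flat_windows):
    counts = np.full((2, 300), 10)
    counts[1, :] = 0
    res = compute_copy_number(counts, flat_windows, n_neighbours=100)
    assert res.low_coverage_cells[1] and not res.low_coverage_cells[0]
    assert np.allclose(res.cn[1], 2.0)


def test_scale_equivariance(flat_windows, rng):
    counts = rng.poisson(8.0, size=(2, 300)) + 1
    res_a = compute_copy_number(counts, flat_windows, n_neighbours=100)
    scaled = counts.copy()
    scaled[0] *= 7
    res_b = compute_copy_number(scaled, flat_windows, n_neighbours=100)
    np.testing.assert_allclose(res_a.cn[0], res_b.cn[0], rtol=1e-12)


def test_diploid_baseline_under_gc_bias():
    # default GC model; depth high enough that Poisson median/mean
    # discreteness is negligible
    sc = gen_counts_matrix(n_cells=150, n_windows=800, depth=20_000, seed=5)
    res = compute_copy_number(sc.counts, sc.windows)
    med = np.median(res.cn, axis=0)
    assert med.min() > 1.8 and med.max() < 2.2


def test_blacklisted_windows_are_dropped():
    sc = gen_counts_matrix(n_cells=5, n_windows=300, depth=2000,
                           gc_coeffs=(0, 0), seed=2)
    sc.windows.loc[10:20, "blacklisted"] = True
    res = compute_copy_number(sc.counts, sc.windows, n_neighbours=100)
    assert res.cn.shape[1] == 300 - 11


class TestGeneAggregation:
    @pytest.fixture
    def cnres(self):
        # non-overlapping 1 Mb windows so gene/window overlap is unambiguous
        from ecdna.cnquant import CopyNumberResult

        windows = sliding_windows({"chr1": 10_000_000},
                                  window=1_000_000, step=1_000_000)
        windows["gc"] = 0.45
        windows["blacklisted"] = False
        cn = np.full((2, len(windows)), 2.0)
        cn[0, 4] = 4.0
        cn[0, 5] = 6.0
        return CopyNumberResult(cn=cn, log2fc=np.log2(cn / 2), windows=windows,
                                cell_ids=np.array(["c0", "c1"]),
                                neighbors=np.zeros((len(windows), 0), int),
                                low_coverage_cells=np.zeros(2, bool))

    def test_gene_within_one_window(self, cnres):
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [4_200_000],
                              "end": [4_700_000], "name": ["g"]})
        out = gene_copy_number(cnres, genes)
        assert out["g"].iloc[0] == pytest.approx(4.0)
        assert out["g"].iloc[1] == pytest.approx(2.0)

    def test_gene_spanning_two_cn_windows(self, cnres):
        # overlaps windows [4M,5M) (CN 4) and [5M,6M) (CN 6): mean is 5
        genes = pd.DataFrame({"chrom": ["chr1"], "start": [4_500_000],
                              "end": [5_500_000], "name": ["g"]})
        out = gene_copy_number(cnres, genes)
        assert out["g"].iloc[0] == pytest.approx(5.0)

    def test_gene_without_windows_is_missing(self, cnres):
        genes = pd.DataFrame({"chrom": ["chrX"], "start": [0],
                              "end": [1000], "name": ["g"]})
        with pytest.warns(UserWarning, match="overlaps no retained window"):
            out = gene_copy_number(cnres, genes)
        assert out["g"].isna().all()


class TestClassifier:
    def test_simulator_leaves_are_ecdna_like(self):
        cn1, _ = cn_profiles_from_simulation(400, seed=8)
        call = classify_amplicon(cn1 + 2.0, "sim")
        assert call.call == "ecDNA-like"
        assert call.var_mean_ratio >= 2.5

    def test_constant_amplification_is_hsr_like(self):
        call = classify_amplicon(cn_profile_fixed(100, 10.0))
        assert call.call == "amplified-non-ecDNA"

    def test_low_mean_is_not_amplified(self, rng):
        call = classify_amplicon(rng.normal(2.0, 2.0, size=100).clip(0))
        assert call.call == "not-amplified"

    def test_too_few_cells_is_indeterminate(self):
        assert classify_amplicon(np.full(5, 30.0)).call == "indeterminate"


class TestAmpliconCorrelation:
    def test_identical_genes_perfectly_correlated(self, rng):
        cn = rng.uniform(4, 30, size=200)
        df = pd.DataFrame({"a": cn, "b": cn})
        res = amplicon_correlation(df, "a", "b", mode="all-cells-log")
        assert res.r == pytest.approx(1.0)

    def test_independent_genes_uncorrelated(self, rng):
        df = pd.DataFrame({"a": rng.uniform(2, 30, 2000),
                           "b": rng.uniform(2, 30, 2000)})
        res = amplicon_correlation(df, "a", "b", mode="all-cells-log")
        assert abs(res.r) < 0.1

    def test_amplified_only_mode_restricts_cells(self, rng):
        a = np.concatenate([np.full(50, 2.0), rng.uniform(4, 30, 100)])
        b = np.concatenate([np.full(50, 2.0), rng.uniform(4, 30, 100)])
        res = amplicon_correlation(pd.DataFrame({"a": a, "b": b}),
                                   "a", "b", mode="amplified-only")
        assert res.n == 100

    def test_too_few_qualifying_cells_undefined(self):
        df = pd.DataFrame({"a": [2.0, 2.0, 5.0], "b": [2.0, 2.0, 5.0]})
        res = amplicon_correlation(df, "a", "b", mode="amplified-only")
        assert not res.defined and res.n == 1


def test_end_to_end_coupled_amplicons_recover_correlation(tmp_path):
    """Counts built from a fully co-segregating two-species population give
    back a strong positive gene-gene correlation through the whole
    pipeline, including the MTX/BED/TSV round trip."""
    cn1, cn2 = cn_profiles_from_simulation(300, seed=17)
    amp = [AmpliconSpec(100, 105, cn1 + 2, "geneA"),
           AmpliconSpec(700, 705, cn2 + 2, "geneB")]
    sc = gen_counts_matrix(n_cells=300, n_windows=1200, amplicons=amp,
                           depth=8000, seed=18)
    sc.write(tmp_path)
    counts, windows, cells = read_window_counts(tmp_path)
    assert counts.shape == (300, 1200)
    windows["blacklisted"] = False
    res = compute_copy_number(counts, windows, cell_ids=cells)
    # gene bodies chosen so every overlapping window lies inside the amplicon
    genes = pd.DataFrame({
        "chrom": ["chrS", "chrS"],
        "start": [102_000_000, 702_000_000],
        "end": [103_000_000, 703_000_000],
        "name": ["geneA", "geneB"]})
    gcn = gene_copy_number(res, genes)
    corr = amplicon_correlation(gcn, "geneA", "geneB", mode="all-cells-log")
    assert corr.r > 0.5
    # classification agrees with the ground-truth profile's class
    assert classify_amplicon(gcn["geneA"]).call == \
        classify_amplicon(cn1 + 2).call == "ecDNA-like"
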