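"""Chi-square comparison, prediction-vector correlation, clustering, CV."""

import numpy as np
import pytest
import scipy.stats

import gapmer as g
from gapmer import (
    chi_square_vs_reference,
    cluster_matrix_types,
    concat_prediction_vectors,
    pearson_correlation,
)
from gapmer.peaks import PredictionResult
from gapmer.stats import cross_validate_rz_from_z


# -- chi-square ---------------------------------------------------------


def test_chi2_equal_counts_is_zero():
    res = chi_square_vs_reference((50, 30, 20), (50, 30, 20))
    assert res.chi2 == 0.0
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 2
    assert res.significance_band == "ns"


def test_chi2_hand_example():
    res = chi_square_vs_reference((60, 25, 15), (50, 30, 20))
    assert res.chi2 == pytest.approx(100 / 50 + 25 / 30 + 25 / 20)
    assert res.p_value == pytest.approx(0.1298, abs=2e-3)
    assert res.significance_band == "ns"


def test_chi2_strong_deviation_significant():
    res = chi_square_vs_reference((90, 5, 5), (50, 30, 20))
    assert res.chi2 == pytest.approx(32 + 625 / 30 + 225 / 20)
    assert res.significance_band == "p<0.01"


def test_chi2_matches_scipy():
    obs, exp = (60, 25, 15), (50, 30, 20)
    ours = chi_square_vs_reference(obs, exp)
    ref = scipy.stats.chisquare(obs, exp)
    assert ours.chi2 == pytest.approx(ref.statistic)
    assert ours.p_value == pytest.approx(ref.pvalue)


def test_chi2_invariant_to_category_order():
    a = chi_square_vs_reference((60, 25, 15), (50, 30, 20))
    b = chi_square_vs_reference((15, 60, 25), (20, 50, 30))
    assert a.chi2 == pytest.approx(b.chi2)


def test_chi2_total_mismatch_errors():
    with pytest.raises(ValueError, match="total"):
        chi_square_vs_reference((60, 25, 15), (50, 30, 21))


def test_chi2_zero_expected_drops_category():
    with pytest.warns(UserWarning, match="expected count 0"):
        res = chi_square_vs_reference((60, 40, 0), (50, 50, 0))
    assert res.df == 1
    assert res.chi2 == pytest.approx(100 / 50 + 100 / 50)


# -- prediction vectors and correlation ---------------------------------


def _pred(peak_id, coverage):
    cov = np.asarray(coverage)
    return PredictionResult(
        peak_id=peak_id, threshold=0.5, site_starts=(), coverage=cov
    )


def test_concat_prediction_vectors():
    v = concat_prediction_vectors(
        [_pred("a", [0, 1, 1, 1, 0]), _pred("b", [0, 0, 0, 0, 0])]
    )
    assert v.tolist() == [0, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    with pytest.raises(ValueError):
        concat_prediction_vectors([])
    with pytest.raises(ValueError, match="coverage length"):
        concat_prediction_vectors([_pred("a", [0, 1]), _pred("b", [0])])


def test_vector_sum_conservation(small_dataset):
    sites, raw_peaks, background = small_dataset
    pat = g.GappedNmer("m")
    bg = g.estimate_background(background, pat)
    wm = g.build_weight_matrix(sites, pat, bg)
    peaks = g.prepare_peaks(raw_peaks, 100)
    results = [g.predict_sites(p.sequence, wm, 0.7, p.peak_id) for p in peaks]
    v = concat_prediction_vectors(results)
    assert v.size == len(peaks) * 100
    assert v.sum() == sum(r.site_count for r in results) * wm.site_length


def test_pearson_examples():
    x = np.arange(4, dtype=float)
    assert pearson_correlation(x, x) == pytest.approx(1.0)
    assert pearson_correlation(x, -x + 7) == pytest.approx(-1.0)
    r = pearson_correlation([0, 1, 2, 3], [1, 1, 3, 3])
    assert r == pytest.approx(0.8944271910, abs=1e-9)


def test_pearson_constant_vector_warns_zero():
    with pytest.warns(UserWarning, match="constant"):
        assert pearson_correlation([1.0, 1.0, 1.0], [0.0, 1.0, 2.0]) == 0.0


def test_pearson_shape_validation():
    with pytest.raises(ValueError):
        pearson_correlation([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_correlation([1], [2])


# -- clustering ---------------------------------------------------------


def brute_force_upgma(d):
    """Naive average-linkage: recompute all pairwise cluster distances."""
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    while len(clusters) > 1:
        keys = list(clusters)
        best = None
        for i_pos, ka in enumerate(keys):
            for kb in keys[i_pos + 1 :]:
                dist = np.mean(
                    [d[a, b] for a in clusters[ka] for b in clusters[kb]]
                )
                if best is None or dist < best[0]:
                    best = (dist, ka, kb)
        dist, ka, kb = best
        merged = clusters.pop(ka) | clusters.pop(kb)
        merges.append((merged, dist))
        clusters[max(keys) + 1] = merged
    return merges


def scipy_merges(d, labels):
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(d, checks=False), method="average")
    sets = {i: frozenset([i]) for i in range(d.shape[0])}
    merges = []
    for step, row in enumerate(Z):
        a, b, h = int(row[0]), int(row[1]), row[2]
        merged = sets[a] | sets[b]
        sets[d.shape[0] + step] = merged
        merges.append((merged, h))
    return merges


@pytest.mark.parametrize("n", [4, 6, 8, 10])
def test_clustering_matches_brute_force(n):
    rng = np.random.default_rng(n)
    r = rng.uniform(-0.9, 0.9, size=(n, n))
    d = 1 - (r + r.T) / 2
    np.fill_diagonal(d, 0.0)
    ours = scipy_merges(d, [str(i) for i in range(n)])
    oracle = brute_force_upgma(d)
    for (set_a, h_a), (set_b, h_b) in zip(ours, oracle):
        assert set_a == set_b
        assert h_a == pytest.approx(h_b)


def test_cluster_two_and_three_leaves():
    two = cluster_matrix_types(np.array([[0, 0.4], [0.4, 0]]), ["a", "b"])
    assert "a" in two and "b" in two and "0.2" in two  # leaves at height d/2
    d3 = np.array([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
    nwk = cluster_matrix_types(d3, ["A", "B", "C"])
    assert "(A:0.05,B:0.05)" in nwk or "(B:0.05,A:0.05)" in nwk


def test_cluster_newick_parses():
    from io import StringIO

    from Bio import Phylo

    rng = np.random.default_rng(1)
    r = rng.uniform(0, 1, size=(6, 6))
    d = (r + r.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"pat{i}" for i in range(6)]
    nwk = cluster_matrix_types(d, labels)
    tree = Phylo.read(StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)


def test_cluster_rejects_asymmetric():
    d = np.array([[0, 0.2], [0.3, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        cluster_matrix_types(d, ["a", "b"])


# -- cross-validation ---------------------------------------------------


def test_cross_validation_subset_size_and_determinism():
    z = np.tile([1.0, 0.5, 0.0, 1.0], 25)  # 100 peaks
    a = cross_validate_rz_from_z(z, fraction=0.5, replicates=10, seed=3)
    b = cross_validate_rz_from_z(z, fraction=0.5, replicates=10, seed=3)
    assert a["subset_size"] == 50
    assert np.array_equal(a["replicate_rz"], b["replicate_rz"])


def test_cross_validation_unbiased():
    rng = np.random.default_rng(0)
    z = rng.choice([0.0, 0.5, 1.0], size=200)
    out = cross_validate_rz_from_z(z, fraction=0.5, replicates=200, seed=1)
    assert out["full_rz"] == pytest.approx(z.mean())
    assert abs(out["mean"] - out["full_rz"]) < 3 * out["std"] / np.sqrt(200) + 0.01


def test_cross_validation_validation():
    with pytest.raises(ValueError):
        cross_validate_rz_from_z([1.0, 0.5], fraction=1.5)
    with pytest.raises(ValueError, match="empty subset"):
        cross_validate_rz_from_z([1.0], fraction=0.5)
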