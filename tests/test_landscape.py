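import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from popmodes import (
    cluster_count_vs_samplesize,
    coclustering_reproducibility,
    density_peak_cluster,
    embed_tsne,
    louvain_jaccard_cluster,
    match_clusters,
    merge_similar_clusters,
    pca_reduce,
)
from popmodes.landscape import _density_peak_stats


def _blob_rows(n_per, centers, noise, dim, seed, n_clusters=3):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    protos = (
        rng.standard_normal((n_clusters, dim)) * 2 if centers is None else centers
    )
    for c, proto in enumerate(protos):
        rows.append(proto + noise * rng.standard_normal((n_per, dim)))
        labels.extend([c] * n_per)
    return np.vstack(rows), np.array(labels)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_exact_low_rank_dimension():
    rng = np.random.default_rng(0)
    basis = rng.standard_normal((2, 40))
    X = rng.standard_normal((30, 2)) @ basis
    load = pca_reduce(X, variance_fraction=0.98)
    assert load.d == 2
    assert load.cumulative_variance >= 0.98


def test_pca_rotation_invariant_spectrum():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((25, 12))
    Q, _ = np.linalg.qr(rng.standard_normal((12, 12)))
    a = pca_reduce(X, n_components=5).explained_variance_ratio
    b = pca_reduce(X @ Q, n_components=5).explained_variance_ratio
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_pca_rejects_degenerate_matrix():
    with pytest.raises(ValueError):
        pca_reduce(np.zeros((5, 8)), n_components=2)


# ---------------------------------------------------------------------------
# t-SNE
# ---------------------------------------------------------------------------

def test_tsne_determinism_duplicates_and_separation():
    X, labels = _blob_rows(60, None, 0.1, 10, seed=2)
    X = np.vstack([X, X[:1]])  # duplicated point
    emb1 = embed_tsne(X, perplexity=30, restarts=2, seed=4)
    emb2 = embed_tsne(X, perplexity=30, restarts=2, seed=4)
    np.testing.assert_array_equal(emb1.coords, emb2.coords)
    assert emb1.kl_divergence == emb1.kl_per_restart.min()
    # duplicate embeds next to its twin
    d_dup = np.linalg.norm(emb1.coords[-1] - emb1.coords[0])
    scale = np.linalg.norm(emb1.coords - emb1.coords.mean(0), axis=1).mean()
    assert d_dup < 0.1 * scale
    sil = silhouette_score(emb1.coords[:-1], labels)
    assert sil > 0.5


def test_tsne_too_few_points_suggests_lower_perplexity():
    with pytest.raises(ValueError, match="perplexity"):
        embed_tsne(np.random.default_rng(0).standard_normal((30, 5)), perplexity=50)


# ---------------------------------------------------------------------------
# density-peak clustering
# ---------------------------------------------------------------------------

def test_density_peak_recovers_three_blobs_auto():
    coords, labels = _blob_rows(100, np.array([[0, 0], [8, 0], [0, 8]]), 0.5, 2, seed=5)
    res = density_peak_cluster(coords)
    assert len(res.centers) == 3
    assert adjusted_rand_score(labels, res.labels) >= 0.95


def test_density_peak_single_blob_auto_gives_one_cluster():
    rng = np.random.default_rng(6)
    res = density_peak_cluster(rng.standard_normal((150, 2)))
    assert len(res.centers) == 1
    assert np.all(res.labels == 0)


def test_density_peak_n_centers_equals_n_points():
    rng = np.random.default_rng(7)
    pts = rng.standard_normal((20, 2))
    res = density_peak_cluster(pts, n_centers=20)
    assert len(np.unique(res.labels)) == 20


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_density_peak_assignment_matches_bruteforce(seed):
    """Assignment equals an independent recursive implementation of the rule:
    each non-center point joins its nearest higher-density neighbor's cluster."""
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [rng.normal(0, 1, (60, 2)), rng.normal([6, 6], 1, (60, 2))]
    )
    res = density_peak_cluster(pts, n_centers=2)
    # independent: recompute densities with the same kernel definition
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    d5 = np.median(np.sort(D, axis=1)[:, 5])
    h = max(0.02 * D.max(), d5)
    rho = np.exp(-((D / h) ** 2)).sum(1) - 1
    labels = np.full(len(pts), -1)
    for ci, c in enumerate(res.centers):
        labels[c] = ci

    def assign(i):
        if labels[i] != -1:
            return labels[i]
        higher = np.nonzero((rho > rho[i]) | ((rho == rho[i]) & (np.arange(len(pts)) < i)))[0]
        j = higher[np.argmin(D[i, higher])]
        labels[i] = assign(j)
        return labels[i]

    for i in range(len(pts)):
        assign(i)
    assert np.array_equal(labels, res.labels)


def test_merge_identical_means_and_unattainable_threshold():
    coords, labels = _blob_rows(50, np.array([[0, 0], [9, 0]]), 0.4, 2, seed=8)
    res = density_peak_cluster(coords, n_centers=2)
    # rows with identical cluster means: give both clusters the same profile
    rows = np.tile(np.sin(np.linspace(0, 3, 30)), (100, 1))
    merged = merge_similar_clusters(res, rows, r_threshold=0.95)
    assert len(np.unique(merged.labels)) == 1
    unmerged = merge_similar_clusters(res, rows, r_threshold=1.01)
    assert len(np.unique(unmerged.labels)) == len(np.unique(res.labels))


def test_merge_planted_duplicate_prototype():
    rng = np.random.default_rng(9)
    t = np.linspace(0, 3, 50)
    proto = {0: np.sin(t), 1: np.sin(t) + 0.02 * rng.standard_normal(50), 2: np.cos(2 * t)}
    labels = np.repeat([0, 1, 2], 40)
    rows = np.stack([proto[c] + 0.01 * rng.standard_normal(50) for c in labels])
    res = density_peak_cluster(
        np.column_stack([labels * 5.0 + rng.normal(0, 0.3, len(labels)), rng.normal(0, 0.3, len(labels))]),
        n_centers=3,
    )
    merged = merge_similar_clusters(res, rows, r_threshold=0.97)
    assert len(np.unique(merged.labels)) == 2


# ---------------------------------------------------------------------------
# cluster matching & reproducibility
# ---------------------------------------------------------------------------

def test_match_clusters_identity_and_permutation():
    rng = np.random.default_rng(10)
    psths = {i: rng.standard_normal(40) for i in range(5)}
    ident = match_clusters(psths, psths)
    assert all(ident[i][0] == i and ident[i][1] == pytest.approx(1.0) for i in psths)
    perm = {i: psths[(i + 2) % 5] for i in range(5)}
    matched = match_clusters(psths, perm)
    assert all(matched[i][0] == (i - 2) % 5 for i in range(5))


def test_match_clusters_extra_cluster_unmatched():
    rng = np.random.default_rng(11)
    b = {i: rng.standard_normal(40) for i in range(3)}
    a = dict(b)
    a[3] = rng.standard_normal(40)
    out = match_clusters(a, b)
    unmatched = [k for k, (m, _) in out.items() if m is None]
    assert len(unmatched) == 1


def test_coclustering_identical_labelings_fully_reproducible():
    labels = np.repeat(np.arange(6), 30)
    rep = coclustering_reproducibility(labels, labels)
    assert sorted(rep["reproducible"]) == list(range(6))
    assert rep["coverage"] == pytest.approx(1.0)


def test_coclustering_permuted_labels_low_coverage():
    rng = np.random.default_rng(12)
    labels = rng.integers(0, 20, size=1000)
    coverages = []
    for s in range(20):
        perm = rng.permutation(labels)
        coverages.append(coclustering_reproducibility(labels, perm)["coverage"])
    assert np.mean(coverages) < 0.2


def test_coclustering_exact_half_split_not_reproducible():
    labels = np.zeros(100, int)
    other = np.repeat([0, 1], 50)
    rep = coclustering_reproducibility(labels, other)
    assert rep["reproducible"] == []


def test_louvain_jaccard_communities_are_blob_pure():
    """The graph-based reference clustering may over-split well-separated
    blobs, but its communities never straddle them, and the labeling is
    deterministic given the seed."""
    coords, labels = _blob_rows(70, np.array([[0, 0], [10, 0], [0, 10]]), 0.6, 2, seed=13)
    lj = louvain_jaccard_cluster(coords, k_nn=12, seed=0)
    lj2 = louvain_jaccard_cluster(coords, k_nn=12, seed=0)
    np.testing.assert_array_equal(lj, lj2)
    for c in np.unique(lj):
        member_blobs = labels[lj == c]
        purity = np.bincount(member_blobs).max() / len(member_blobs)
        assert purity > 0.95


# ---------------------------------------------------------------------------
# saturation curve
# ---------------------------------------------------------------------------

def test_cluster_count_saturates_at_prototype_count():
    rows, _ = _blob_rows(70, None, 0.05, 16, seed=14)
    curve = cluster_count_vs_samplesize(rows, fractions=[0.7, 1.0], seeds=[0, 1])
    assert curve[1.0] == pytest.approx(3.0, abs=0.5)
    assert curve[0.7] <= curve[1.0] + 0.5


def test_single_prototype_flat_curve_at_one():
    rng = np.random.default_rng(15)
    rows = rng.standard_normal(12) + 0.05 * rng.standard_normal((80, 12))
    curve = cluster_count_vs_samplesize(rows, fractions=[1.0], seeds=[0, 1])
    assert curve[1.0] == pytest.approx(1.0, abs=0.01)
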