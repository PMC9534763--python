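"""Response-profile landscape: PCA, t-SNE embedding and density-peak clustering.

Response profiles (rows of the normalized PSTH matrix) are reduced to their
top principal components, embedded in 2-D with t-SNE (cosine metric, best of
several restarts by Kullback-Leibler divergence), and clustered with the
density-peak algorithm: every point gets a local density rho and the distance
delta to the nearest point of higher density; cluster centers are extremes of
gamma = rho * delta and each remaining point joins the cluster of its nearest
higher-density neighbor.  Center selection is automatic by default (largest
gap in the sorted gamma sequence) with manual selection still supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .psth import PSTHMatrix

__all__ = [
    "Loadings",
    "Embedding2D",
    "DensityPeakResult",
    "pca_reduce",
    "embed_tsne",
    "density_peak_cluster",
    "merge_similar_clusters",
    "match_clusters",
    "louvain_jaccard_cluster",
    "coclustering_reproducibility",
    "cluster_count_vs_samplesize",
]


@dataclass
class Loadings:
    loadings: np.ndarray  # (n_units, d)
    explained_variance_ratio: np.ndarray
    d: int

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance_ratio.sum())


def pca_reduce(
    matrix: PSTHMatrix | np.ndarray,
    n_components: int | None = None,
    variance_fraction: float | None = None,
) -> Loadings:
    """Project rows onto the top principal components.

    Exactly one of ``n_components`` / ``variance_fraction`` selects the
    dimensionality; with a variance target, d is the smallest dimension whose
    cumulative explained variance reaches it.
    """
    X = matrix.matrix if isinstance(matrix, PSTHMatrix) else np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if (n_components is None) == (variance_fraction is None):
        raise ValueError("specify exactly one of n_components / variance_fraction")
    max_d = min(X.shape)
    pca = PCA(n_components=max_d, svd_solver="full")
    Z = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    if evr[0] != evr[0] or pca.explained_variance_[0] < 1e-15:
        raise ValueError("degenerate (rank-0) matrix")
    if variance_fraction is not None:
        cum = np.cumsum(evr)
        d = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
        d = min(d, max_d)
    else:
        d = min(n_components, max_d)
    return Loadings(loadings=Z[:, :d], explained_variance_ratio=evr[:d], d=d)


@dataclass
class Embedding2D:
    coords: np.ndarray  # (n, 2)
    perplexity: float
    kl_divergence: float
    restart_index: int
    kl_per_restart: np.ndarray


def embed_tsne(
    loadings: Loadings | np.ndarray,
    perplexity: float = 50.0,
    metric: str = "cosine",
    restarts: int = 10,
    seed: int = 0,
) -> Embedding2D:
    """2-D t-SNE; the restart (seeds seed..seed+restarts-1) with the lowest
    KL divergence is returned."""
    X = loadings.loadings if isinstance(loadings, Loadings) else np.asarray(loadings, float)
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"n={n} too small for perplexity {perplexity}; need n >= 3*perplexity "
            f"(try perplexity <= {n // 3})"
        )
    best = None
    kls = []
    for i in range(restarts):
        ts = TSNE(
            n_components=2,
            perplexity=perplexity,
            metric=metric,
            init="random",
            random_state=seed + i,
        )
        Y = ts.fit_transform(X)
        kls.append(float(ts.kl_divergence_))
        if best is None or kls[-1] < best[1]:
            best = (Y, kls[-1], i)
    return Embedding2D(
        coords=best[0],
        perplexity=perplexity,
        kl_divergence=best[1],
        restart_index=best[2],
        kl_per_restart=np.array(kls),
    )


@dataclass
class DensityPeakResult:
    labels: np.ndarray  # (n,)
    rho: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    centers: np.ndarray  # indices of cluster centers
    halo: np.ndarray  # bool, low-density border points


def _density_peak_stats(
    coords: np.ndarray, bandwidth_fraction: float = 0.02
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    D = squareform(pdist(coords))
    n = D.shape[0]
    diam = float(D.max())
    if diam == 0:
        rho = np.full(n, float(n))
        delta = np.zeros(n)
        return rho, delta, np.full(n, -1, dtype=int), D
    # bandwidth: fraction of the diameter, floored at the median 5th-neighbor
    # distance so sparse embeddings still get a meaningful density estimate
    k5 = min(5, n - 1)
    d5 = np.median(np.sort(D, axis=1)[:, k5])
    h = max(bandwidth_fraction * diam, d5)
    rho = np.exp(-((D / h) ** 2)).sum(axis=1) - 1.0
    # deterministic ordering: by density, ties by index
    order = np.lexsort((np.arange(n), -rho))
    delta = np.empty(n)
    nn_higher = np.full(n, -1, dtype=int)
    delta[order[0]] = D[order[0]].max()
    for rank in range(1, n):
        i = order[rank]
        higher = order[:rank]
        j = higher[np.argmin(D[i, higher])]
        delta[i] = D[i, j]
        nn_higher[i] = j
    return rho, delta, nn_higher, D


def density_peak_cluster(
    embedding: Embedding2D | np.ndarray,
    n_centers: int | None = None,
    manual_centers: list[int] | None = None,
    bandwidth_fraction: float = 0.02,
    compute_halo: bool = True,
) -> DensityPeakResult:
    """Density-peak clustering of a 2-D embedding.

    Local density uses a Gaussian kernel with bandwidth a fraction of the
    embedding diameter.  Centers are chosen either manually (a list of point
    indices), by count (the ``n_centers`` largest gamma = rho*delta), or
    automatically by the largest gap in the sorted gamma sequence.  Every
    non-center point is assigned to the cluster of its nearest neighbor of
    higher density.  Halo points lie within one bandwidth of another cluster
    and below the maximal border density.
    """
    coords = embedding.coords if isinstance(embedding, Embedding2D) else np.asarray(embedding, float)
    n = coords.shape[0]
    if n < 10:
        raise ValueError("need at least 10 points")
    rho, delta, nn_higher, D = _density_peak_stats(coords, bandwidth_fraction)
    gamma = rho * delta
    if float(D.max()) == 0:
        warnings.warn("all points identical; single cluster", stacklevel=2)
        return DensityPeakResult(
            labels=np.zeros(n, int), rho=rho, delta=delta, gamma=gamma,
            centers=np.array([0]), halo=np.zeros(n, bool),
        )
    order_gamma = np.argsort(-gamma, kind="stable")
    if manual_centers is not None:
        centers = np.asarray(manual_centers, int)
    elif n_centers is not None:
        centers = order_gamma[: min(n_centers, n)]
    else:
        # largest multiplicative gap in the sorted gamma sequence; the ratio
        # is scale-free, which keeps a lone dominant peak from being split
        g = np.maximum(gamma[order_gamma], 1e-12)
        upper = max(1, n // 2)
        ratios = g[:upper] / g[1 : upper + 1]
        k = int(np.argmax(ratios)) + 1
        centers = order_gamma[:k]

    labels = np.full(n, -1, int)
    for c_idx, c in enumerate(centers):
        labels[c] = c_idx
    order = np.lexsort((np.arange(n), -rho))
    for i in order:
        if labels[i] == -1:
            labels[i] = labels[nn_higher[i]]

    halo = np.zeros(n, bool)
    if compute_halo and len(centers) > 1:
        h = bandwidth_fraction * float(D.max())
        border_rho = np.zeros(len(centers))
        near_other = (D < h) & (labels[None, :] != labels[:, None])
        is_border = near_other.any(axis=1)
        for c_idx in range(len(centers)):
            mask = (labels == c_idx) & is_border
            if mask.any():
                border_rho[c_idx] = rho[mask].max()
        halo = rho < border_rho[labels]
        halo[centers] = False
    return DensityPeakResult(
        labels=labels, rho=rho, delta=delta, gamma=gamma,
        centers=np.asarray(centers), halo=halo,
    )


def merge_similar_clusters(
    result: DensityPeakResult,
    psth_rows: np.ndarray,
    r_threshold: float = 0.95,
) -> DensityPeakResult:
    """Greedily merge cluster pairs whose mean response profiles correlate
    above the threshold, highest correlation first, recomputing means after
    each merge."""
    labels = result.labels.copy()

    def cluster_means(lbl: np.ndarray) -> dict[int, np.ndarray]:
        return {c: psth_rows[lbl == c].mean(axis=0) for c in np.unique(lbl)}

    while True:
        means = cluster_means(labels)
        ids = sorted(means)
        if len(ids) < 2:
            break
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                ma, mb = means[a], means[b]
                if np.std(ma) == 0 or np.std(mb) == 0:
                    continue
                r = float(np.corrcoef(ma, mb)[0, 1])
                if best is None or r > best[0]:
                    best = (r, a, b)
        if best is None or best[0] < r_threshold:
            break
        _, a, b = best
        labels[labels == b] = a
    # relabel compactly, keep center list for surviving clusters
    uniq = np.unique(labels)
    remap = {c: i for i, c in enumerate(uniq)}
    new_labels = np.array([remap[c] for c in labels])
    centers = [c for c in result.centers if remap.get(result.labels[c]) is not None]
    kept = []
    seen = set()
    for c in centers:
        lbl = new_labels[c]
        if lbl not in seen:
            seen.add(lbl)
            kept.append(c)
    return replace(result, labels=new_labels, centers=np.asarray(kept))


def match_clusters(
    psths_a: dict[int, np.ndarray], psths_b: dict[int, np.ndarray]
) -> dict[int, tuple[int | None, float]]:
    """Greedy best-correlation matching of cluster mean profiles A -> B.

    Pairs are taken in order of decreasing Pearson correlation; once a B
    cluster is taken, the next-best available match is used.  A clusters left
    without an available partner map to ``(None, nan)``.
    """
    if not psths_a or not psths_b:
        raise ValueError("empty cluster set")
    pairs = []
    for a, pa in psths_a.items():
        for b, pb in psths_b.items():
            r = float(np.corrcoef(pa, pb)[0, 1]) if np.std(pa) > 0 and np.std(pb) > 0 else -np.inf
            pairs.append((r, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    out: dict[int, tuple[int | None, float]] = {}
    taken_b: set[int] = set()
    for r, a, b in pairs:
        if a in out or b in taken_b:
            continue
        out[a] = (b, r)
        taken_b.add(b)
    for a in psths_a:
        out.setdefault(a, (None, float("nan")))
    return out


def louvain_jaccard_cluster(
    features: np.ndarray, k_nn: int = 15, seed: int = 0
) -> np.ndarray:
    """Graph-based reference clustering: Jaccard-weighted kNN graph + Louvain
    community detection.  Serves as the second method for reproducibility
    scoring; any labeling can be supplied instead."""
    import igraph as ig

    X = np.asarray(features, float)
    n = X.shape[0]
    k = min(k_nn, n - 1)
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nbrs.kneighbors(X)
    neigh = [set(row[1:]) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i, 1:]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            if inter:
                edges.append((i, j))
                weights.append(inter / union)
    g = ig.Graph(n=n, edges=edges)
    rng_state = np.random.default_rng(seed)
    ig.set_random_number_generator(_IgraphRng(rng_state))
    part = g.community_multilevel(weights=weights)
    return np.asarray(part.membership, int)


class _IgraphRng:
    """Adapter handing a seeded numpy generator to igraph."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng

    def random(self) -> float:
        return float(self._rng.random())

    def randint(self, a, b=None):
        if b is None:
            return int(self._rng.integers(0, a))
        return int(self._rng.integers(a, b + 1))

    def gauss(self, mu: float, sigma: float) -> float:
        return float(self._rng.normal(mu, sigma))


def coclustering_reproducibility(
    labels_a: np.ndarray, labels_b: np.ndarray
) -> dict:
    """Cluster reproducibility across two labelings of the same units.

    For each cluster in A the matching B cluster is the one with the largest
    overlap, accepted only if more than half of the B cluster's units lie in
    the A cluster; the A cluster is reproducible if, additionally, more than
    half of its own units are captured by that match (both inequalities
    strict).  Returns the matched pairs, reproducible-cluster list and the
    fraction of units covered by reproducible clusters.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same unit set")
    report = {"matches": {}, "reproducible": [], "coverage": 0.0}
    covered = 0
    for ca in np.unique(a):
        in_a = a == ca
        best_cb, best_overlap = None, 0
        for cb in np.unique(b[in_a]):
            overlap = int(np.sum(in_a & (b == cb)))
            if overlap > best_overlap:
                best_overlap, best_cb = overlap, cb
        if best_cb is None:
            continue
        size_b = int(np.sum(b == best_cb))
        # matching cluster: >50% of B's units fall inside the A cluster
        if best_overlap <= 0.5 * size_b:
            report["matches"][int(ca)] = None
            continue
        report["matches"][int(ca)] = int(best_cb)
        # reproducible: >50% of A's units captured by the match
        if best_overlap > 0.5 * int(in_a.sum()):
            report["reproducible"].append(int(ca))
            covered += int(in_a.sum())
    report["coverage"] = covered / a.size
    return report


def cluster_count_vs_samplesize(
    matrix: PSTHMatrix | np.ndarray,
    fractions: list[float],
    seeds: list[int],
    perplexity: float = 30.0,
    n_pcs: int = 20,
    tsne_restarts: int = 2,
) -> dict[float, float]:
    """Mean auto-selected cluster count as a function of subsample size."""
    X = matrix.matrix if isinstance(matrix, PSTHMatrix) else np.asarray(matrix, float)
    n = X.shape[0]
    out: dict[float, float] = {}
    for frac in fractions:
        counts = []
        for seed in seeds:
            rng = np.random.default_rng(seed)
            m = max(int(round(frac * n)), 10)
            idx = rng.choice(n, size=min(m, n), replace=False)
            sub = X[idx]
            load = pca_reduce(sub, n_components=min(n_pcs, min(sub.shape)))
            perp = min(perplexity, (sub.shape[0] - 1) // 3)
            emb = embed_tsne(load, perplexity=perp, restarts=tsne_restarts, seed=seed)
            res = density_peak_cluster(emb)
            counts.append(len(res.centers))
        out[frac] = float(np.mean(counts))
    return out
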