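"""Functional populations from activity-mode coding vectors.

A neuron's coding vector is its row of weights across the seven activity
modes.  This module quantifies the geometry of those vectors (pairwise-mode
angle distributions against a random-mixture reference), partitions neurons
into functional populations by k-means on absolute weights (k chosen by
silhouette), names populations by the mode whose variance they carry most of,
and relates populations to the t-SNE landscape and to cortical depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .modes import MODE_ORDER, ModeSet
from .session import Unit

__all__ = [
    "ModeWeightVectors",
    "FunctionalPopulations",
    "pair_angle_distribution",
    "kmeans_populations",
    "population_variance_carried",
    "classify_by_embedding",
    "depth_distribution",
]


@dataclass
class ModeWeightVectors:
    weights: np.ndarray  # (n, 7)
    unit_ids: list[str]
    mode_names: tuple[str, ...] = MODE_ORDER

    @classmethod
    def from_modeset(cls, modeset: ModeSet) -> "ModeWeightVectors":
        return cls(weights=modeset.weights.copy(), unit_ids=list(modeset.unit_ids), mode_names=modeset.names)

    @property
    def vector_length(self) -> np.ndarray:
        return np.linalg.norm(self.weights, axis=1)


def pair_angle_distribution(
    weights: ModeWeightVectors | np.ndarray,
    mode_a: str | int,
    mode_b: str | int,
    reference_angles: np.ndarray | None = None,
    top_fraction: float = 0.2,
    alternative: str = "greater",
) -> tuple[np.ndarray, float | None]:
    """Angles of two-mode coding vectors, folded into [0, 90] degrees.

    Only the ``top_fraction`` of neurons ranked by two-mode vector length are
    kept (weak neurons are uniformly distributed regardless of geometry); the
    angle is atan2(|w_b|, |w_a|).  If a reference distribution (angles of the
    matched random-mixture population) is given, a one-sided two-sample
    Kolmogorov-Smirnov p-value is returned (default alternative 'greater':
    excess mass at small angles relative to the reference, the signature of
    0/90-degree segregation).
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if isinstance(weights, ModeWeightVectors):
        names = weights.mode_names
        W = weights.weights
        ia = names.index(mode_a) if isinstance(mode_a, str) else mode_a
        ib = names.index(mode_b) if isinstance(mode_b, str) else mode_b
    else:
        W = np.asarray(weights, float)
        ia, ib = int(mode_a), int(mode_b)
    wa, wb = np.abs(W[:, ia]), np.abs(W[:, ib])
    length = np.hypot(wa, wb)
    n_keep = max(1, int(round(top_fraction * len(length))))
    keep = np.argsort(-length, kind="stable")[:n_keep]
    angles = np.degrees(np.arctan2(wb[keep], wa[keep]))
    p = None
    if reference_angles is not None:
        # fold both to the angular distance from the nearer axis (0 for a pure
        # single-mode neuron, 45 for perfectly mixed), so 0- and 90-degree
        # peaks both become excess mass at small values; alternative 'greater'
        # (observed CDF above the reference) then detects segregation
        obs = 45.0 - np.abs(angles - 45.0)
        ref = 45.0 - np.abs(np.asarray(reference_angles, float) - 45.0)
        p = float(ks_2samp(obs, ref, alternative=alternative).pvalue)
    return angles, p


@dataclass
class FunctionalPopulations:
    labels: np.ndarray  # (n,)
    k: int
    population_names: dict[int, str]
    silhouette_by_k: dict[int, float]
    variance_carried: np.ndarray | None = None  # (k, 7)
    mode_names: tuple[str, ...] = MODE_ORDER


def kmeans_populations(
    weights: ModeWeightVectors | np.ndarray,
    k_range: tuple[int, int] = (2, 12),
    seed: int = 0,
    restarts: int = 50,
    projection_timecourses: dict[str, np.ndarray] | None = None,
) -> FunctionalPopulations:
    """Partition neurons into functional populations by k-means on |weights|.

    k is chosen by the largest Euclidean silhouette over ``k_range``.  When
    per-mode projection time courses are available the populations are named
    after the mode whose projection variance they dominate (ties to the larger
    population); otherwise a squared-weight proxy is used.
    """
    W = weights.weights if isinstance(weights, ModeWeightVectors) else np.asarray(weights, float)
    names = weights.mode_names if isinstance(weights, ModeWeightVectors) else MODE_ORDER
    X = np.abs(W)
    n = X.shape[0]
    if n < k_range[1]:
        raise ValueError(f"n={n} too small for k_range up to {k_range[1]}")
    if np.allclose(X, X[0]):
        raise ValueError("all coding vectors identical; silhouette undefined")
    sil: dict[int, float] = {}
    best = None
    for k in range(k_range[0], k_range[1] + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            continue
        s = float(silhouette_score(X, lab))
        sil[k] = s
        if best is None or s > best[0]:
            best = (s, k, lab)
    _, k_star, labels = best

    # variance carried per (population, mode): restricted-projection variance
    # over full-projection variance; proxy = squared weight mass when no
    # projection time courses are supplied
    if projection_timecourses is not None:
        vc = _variance_carried_from_projections(W, labels, k_star, names, projection_timecourses)
    else:
        full = (W**2).sum(axis=0)
        vc = np.stack([(W[labels == c] ** 2).sum(axis=0) / full for c in range(k_star)])
    pop_names: dict[int, str] = {}
    sizes = np.bincount(labels, minlength=k_star)
    for j, m in enumerate(names):
        order = np.lexsort((-sizes, -vc[:, j]))
        c = int(order[0])
        if c not in pop_names:
            pop_names[c] = m
    for c in range(k_star):
        pop_names.setdefault(c, f"population_{c}")
    return FunctionalPopulations(
        labels=labels, k=k_star, population_names=pop_names,
        silhouette_by_k=sil, variance_carried=vc, mode_names=names,
    )


def _variance_carried_from_projections(
    W: np.ndarray,
    labels: np.ndarray,
    k: int,
    names: tuple[str, ...],
    activity: dict[str, np.ndarray] | np.ndarray,
) -> np.ndarray:
    A = (
        np.concatenate(list(activity.values()), axis=1)
        if isinstance(activity, dict)
        else np.asarray(activity, float)
    )
    vc = np.zeros((k, len(names)))
    for j in range(len(names)):
        full = W[:, j] @ A
        vfull = float(np.var(full))
        for c in range(k):
            wr = np.where(labels == c, W[:, j], 0.0)
            vc[c, j] = float(np.var(wr @ A)) / vfull if vfull > 0 else np.nan
    return vc


def population_variance_carried(
    populations: FunctionalPopulations,
    modeset: ModeSet,
    activity: np.ndarray | dict[str, np.ndarray],
) -> np.ndarray:
    """Fraction of each mode's projection variance carried by each population.

    The restricted projection sets out-of-population weights to zero; the
    fraction is var(restricted projection) / var(full projection) over the
    supplied activity time courses.  Restricted variances need not sum to 1.
    """
    return _variance_carried_from_projections(
        modeset.weights, populations.labels, populations.k, modeset.names, activity
    )


def classify_by_embedding(
    labels: np.ndarray,
    coords: np.ndarray,
    k_nn: int = 10,
    bootstrap_n: int = 1000,
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Leave-one-out k-nearest-neighbor classification in the embedding.

    Each point is classified by majority vote of its ``k_nn`` nearest
    neighbors (ties broken by the smaller summed neighbor distance, then by
    label order — deterministic); returns per-class accuracy with a
    neuron-bootstrap standard error.
    """
    labels = np.asarray(labels)
    coords = np.asarray(coords, float)
    n = len(labels)
    classes = np.unique(labels)
    for c in classes:
        if np.sum(labels == c) < k_nn:
            warnings.warn(f"class {c} has fewer than {k_nn} members", stacklevel=2)
    D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(D, np.inf)
    nn = np.argsort(D, axis=1, kind="stable")[:, :k_nn]
    pred = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        neigh = labels[nn[i]]
        cand, counts = np.unique(neigh, return_counts=True)
        top = cand[counts == counts.max()]
        if len(top) == 1:
            pred[i] = top[0]
        else:
            sums = [D[i, nn[i][neigh == c]].sum() for c in top]
            pred[i] = top[int(np.argmin(sums))]
    correct = pred == labels
    rng = np.random.default_rng(seed)
    out: dict[int, tuple[float, float]] = {}
    for c in classes:
        mask = labels == c
        acc = float(correct[mask].mean())
        idx = np.nonzero(mask)[0]
        boots = rng.choice(idx, size=(bootstrap_n, len(idx)), replace=True)
        se = float(correct[boots].mean(axis=1).std())
        out[int(c) if np.issubdtype(labels.dtype, np.integer) else c] = (acc, se)
    return out


def depth_distribution(
    labels: np.ndarray,
    units: list[Unit],
    bin_edges_um: np.ndarray,
) -> dict[int, np.ndarray]:
    """Depth histograms per population, normalized within population.

    Fractions are relative to all neurons of each population, so each
    histogram sums to 1.
    """
    depths = np.array([u.depth_um for u in units])
    out: dict[int, np.ndarray] = {}
    for c in np.unique(labels):
        h, _ = np.histogram(depths[labels == c], bins=bin_edges_um)
        total = h.sum()
        out[int(c)] = h / total if total else h.astype(float)
    return out
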