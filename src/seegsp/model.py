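"""Quadrant features, clustering, and the implantation-adequacy probability.

The SP map is summarized by the mean positive pixel intensity in each of
its four quadrants (Q1 top-left, Q2 top-right, Q3 bottom-right, Q4
bottom-left): a well-sampled focal implantation concentrates mass on the
top-left/diagonal, so its Q2 and Q4 are small.  The quadrant subset that
maximizes Dunn's index under 2-means clustering is selected as the feature
space (expected: Q1, Q2, Q4).  A bootstrapped k-means yields two stable
centroids — the one nearer the feature-space origin models adequate
sampling — and Student-t fits to within-cluster centroid distances turn a
new patient's position into a probability of adequate implantation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .core import FrameworkConfig
from .ranked import SPMap

__all__ = [
    "MapFeatures",
    "ClusterModel",
    "quadrant_features",
    "dunn_index",
    "select_feature_subset",
    "fit_cluster_model",
    "probability_adequate",
    "classify_by_cluster",
]

QUADRANTS = ("q1", "q2", "q3", "q4")


@dataclass(frozen=True)
class MapFeatures:
    """Mean positive intensity per SP-map quadrant (Q3 kept for selection)."""

    patient_id: str
    q1: float
    q2: float
    q3: float
    q4: float

    def vector(self, quadrants: Sequence[str] = ("q1", "q2", "q4")) -> np.ndarray:
        return np.array([getattr(self, q) for q in quadrants], dtype=float)


@dataclass(frozen=True)
class ClusterModel:
    """Bootstrapped 2-means centroids plus per-cluster t distance models.

    ``c1_hat`` is the centroid closer to the origin (adequate sampling);
    ``t1``/``t2`` are ``(df, loc, scale)`` triples of location-scale
    Student-t fits to the within-cluster distances to the respective
    centroid.  ``df = inf`` encodes the normal fallback used when a
    cluster has fewer than 4 members.
    """

    c1_hat: np.ndarray
    c2_hat: np.ndarray
    t1: tuple[float, float, float]
    t2: tuple[float, float, float]
    selected_features: tuple[str, ...]


def quadrant_features(sp_map: SPMap, patient_id: str = "") -> MapFeatures:
    """Mean of strictly positive pixels per quadrant; 0 for empty quadrants.

    The image splits at the row and column midpoints.  Quadrants are
    numbered counter-clockwise from top-left: Q1 top-left, Q2 top-right,
    Q3 bottom-right, Q4 bottom-left, so the diagonal signature of a good
    map lives in Q1/Q3 and leakage shows up in Q2/Q4.
    """
    if sp_map.degenerate:
        raise ValueError("cannot extract quadrant features from a degenerate map")
    img = sp_map.image
    rmid, cmid = img.shape[0] // 2, img.shape[1] // 2
    blocks = {
        "q1": img[:rmid, :cmid],
        "q2": img[:rmid, cmid:],
        "q3": img[rmid:, cmid:],
        "q4": img[rmid:, :cmid],
    }
    vals = {}
    for q, block in blocks.items():
        pos = block[block > 0]
        vals[q] = float(pos.mean()) if pos.size else 0.0
    return MapFeatures(patient_id=patient_id, **vals)


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Dunn's cluster-validity index.

    Minimum between-cluster single-linkage distance divided by the maximum
    within-cluster diameter.  A clustering whose every cluster has zero
    diameter (all-coincident points) returns +inf.
    """
    pts = np.asarray(points, dtype=float)
    labs = np.asarray(labels)
    uniq = np.unique(labs)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    diam = 0.0
    for u in uniq:
        grp = pts[labs == u]
        if len(grp) > 1:
            d = np.linalg.norm(grp[:, None, :] - grp[None, :, :], axis=-1)
            diam = max(diam, float(d.max()))
    sep = np.inf
    for a, b in combinations(uniq, 2):
        ga, gb = pts[labs == a], pts[labs == b]
        d = np.linalg.norm(ga[:, None, :] - gb[None, :, :], axis=-1)
        sep = min(sep, float(d.min()))
    if diam == 0.0:
        return np.inf
    return sep / diam


def select_feature_subset(
    features: Sequence[MapFeatures],
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, ...]:
    """Quadrant subset (size >= 2) maximizing Dunn's index under 2-means.

    Ties break toward the smaller subset, then lexicographically, so the
    selection is deterministic.
    """
    if len(features) < 4:
        raise ValueError("need at least 4 patients for feature selection")
    if rng is None:
        rng = np.random.default_rng(0)
    full = np.array([[getattr(f, q) for q in QUADRANTS] for f in features])
    if np.allclose(full.std(axis=0), 0):
        raise ValueError("degenerate features: no variance in any quadrant")
    best: tuple[float, int, tuple[str, ...]] | None = None
    seed = int(rng.integers(0, 2**31 - 1))
    for size in (2, 3, 4):
        for combo in combinations(range(4), size):
            sub = full[:, combo]
            km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(sub)
            if len(np.unique(km.labels_)) < 2:
                continue
            di = dunn_index(sub, km.labels_)
            names = tuple(QUADRANTS[i] for i in combo)
            key = (-di, size, names)
            if best is None or key < (-best[0], best[1], best[2]):
                best = (di, size, names)
    if best is None:
        raise ValueError("feature selection failed on degenerate input")
    return best[2]


def _fit_t(distances: np.ndarray) -> tuple[float, float, float]:
    """Location-scale Student-t MLE with df >= 1; normal fallback for n < 4."""
    d = np.asarray(distances, dtype=float)
    if d.size < 4 or d.std() == 0.0:
        scale = d.std() if d.size and d.std() > 0 else 1e-6
        return (np.inf, float(d.mean()) if d.size else 0.0, float(scale))
    df, loc, scale = stats.t.fit(d)
    if df < 1.0:
        df, loc, scale = stats.t.fit(d, f0=1.0)
    return float(df), float(loc), float(scale)


def fit_cluster_model(
    features: Sequence[MapFeatures],
    cfg: FrameworkConfig,
    rng: Optional[np.random.Generator] = None,
    outcome_labels: Optional[Mapping[str, str]] = None,
    selected: Sequence[str] = ("q1", "q2", "q4"),
) -> ClusterModel:
    """Bootstrapped 2-means in the selected quadrant space plus t fits.

    Each of ``cfg.kmeans_bootstrap`` iterations subsamples
    ``cfg.kmeans_subsample`` of the patients (stratified by outcome when
    labels are supplied) and runs k-means (k=2, k-means++).  Iteration
    centroids are aligned to the first iteration's pair by
    minimal-displacement matching before averaging; the averaged centroid
    nearer the origin becomes ``c1_hat``.  Student-t distributions are
    then fit to the distances of each cluster's members to its centroid.
    """
    if len(features) < 6:
        raise ValueError("need at least 6 patients to fit the cluster model")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    X = np.array([f.vector(selected) for f in features])
    if np.allclose(X, X[0]):
        raise ValueError("degenerate clustering: all feature points identical")

    n = len(X)
    n_sub = max(2, round(cfg.kmeans_subsample * n))
    if outcome_labels:
        strata: dict[str, list[int]] = {}
        for i, f in enumerate(features):
            strata.setdefault(outcome_labels.get(f.patient_id, "unknown"), []).append(i)
    else:
        strata = {"all": list(range(n))}

    ref_pair: Optional[np.ndarray] = None
    acc = np.zeros((2, X.shape[1]))
    kept = 0
    for _ in range(cfg.kmeans_bootstrap):
        idx: list[int] = []
        for members in strata.values():
            k = max(1, round(cfg.kmeans_subsample * len(members)))
            idx.extend(rng.choice(members, size=min(k, len(members)), replace=False))
        if len(idx) < 2:
            idx = list(rng.choice(n, size=n_sub, replace=False))
        seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=2, n_init=5, random_state=seed).fit(X[idx])
        cents = km.cluster_centers_
        if ref_pair is None:
            # anchor orientation: nearer-origin centroid first
            order = np.argsort(np.linalg.norm(cents, axis=1))
            ref_pair = cents[order]
            acc += ref_pair
        else:
            straight = np.linalg.norm(cents - ref_pair, axis=1).sum()
            swapped = np.linalg.norm(cents[::-1] - ref_pair, axis=1).sum()
            acc += cents if straight <= swapped else cents[::-1]
        kept += 1
    mean_cents = acc / kept
    order = np.argsort(np.linalg.norm(mean_cents, axis=1))
    c1, c2 = mean_cents[order[0]], mean_cents[order[1]]

    d1 = np.linalg.norm(X - c1, axis=1)
    d2 = np.linalg.norm(X - c2, axis=1)
    in_c1 = d1 <= d2
    t1 = _fit_t(d1[in_c1])
    t2 = _fit_t(d2[~in_c1]) if np.any(~in_c1) else _fit_t(d2)
    return ClusterModel(
        c1_hat=c1, c2_hat=c2, t1=t1, t2=t2, selected_features=tuple(selected)
    )


def _tail(d: float, params: tuple[float, float, float]) -> float:
    df, loc, scale = params
    if np.isinf(df):
        return float(stats.norm.sf(d, loc=loc, scale=scale))
    return float(stats.t.sf(d, df, loc=loc, scale=scale))


def probability_adequate(f: MapFeatures, model: ClusterModel) -> float:
    """Probability that the implantation adequately sampled the focus.

    ``p1`` is the upper-tail probability of the distance to ``c1_hat``
    under the cluster-1 t model (large when the patient sits inside the
    adequate cluster), ``p2`` likewise for ``c2_hat``; the combined score
    ``(p1 + (1 - p2)) / 2`` realizes "in cluster 1 but not in cluster 2".
    """
    x = f.vector(model.selected_features)
    d1 = float(np.linalg.norm(x - model.c1_hat))
    d2 = float(np.linalg.norm(x - model.c2_hat))
    p1 = _tail(d1, model.t1)
    p2 = _tail(d2, model.t2)
    return float(np.clip((p1 + (1.0 - p2)) / 2.0, 0.0, 1.0))


def classify_by_cluster(f: MapFeatures, model: ClusterModel) -> str:
    """Nearest-centroid call; ties resolve optimistically to well_sampled."""
    x = f.vector(model.selected_features)
    d1 = np.linalg.norm(x - model.c1_hat)
    d2 = np.linalg.norm(x - model.c2_hat)
    return "well_sampled" if d1 <= d2 else "poorly_sampled"
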