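"""Habitat clustering: feature construction, k-means, magnitude ordering.

In-ROI pixels of one or two parameter maps are z-scored per channel
(optionally with spatially weighted pixel coordinates appended) and
partitioned with k-means (Lloyd's algorithm, k-means++ seeding, multiple
restarts). Clusters are then relabelled so that label 1..k ascends with
the per-cluster mean magnitude of the summed intensity channels — the
highest-numbered habitat always corresponds to the highest magnitude.
Pixels with pyruvate SNR below a floor are matched to background
(label 0) before clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .maps import DegenerateInputError, ParameterMap, TumourROI, mask_map


@dataclass
class FeatureMatrix:
    """Pixel-by-channel features for one slice's in-mask pixels."""

    X: np.ndarray                 # (n_pixels, n_channels [+2])
    channel_names: list[str]
    pixel_index: np.ndarray       # flat row-major indices into the grid
    shape: tuple[int, int]
    n_intensity: int              # leading columns that are intensity channels

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != self.pixel_index.size:
            raise ValueError("feature matrix rows must match pixel index list")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")


@dataclass
class HabitatMap:
    """Integer label image: 0 = background/excluded, 1..k ordered by magnitude."""

    labels: np.ndarray
    k: int
    ordering_stat: np.ndarray     # per-habitat mean magnitude, ascending
    slice_id: str = "0"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 0 or self.labels.max() > self.k:
            raise ValueError("labels must lie in {0..k}")

    @property
    def clustered_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    wss: float
    n_iter: int
    objective_history: list[float]


def build_features(
    maps: ParameterMap | list[ParameterMap],
    roi: TumourROI,
    snr_floor: float = 5.0,
    spatial_weight: float = 0.0,
    snr_reference: ParameterMap | None = None,
    k: int = 3,
) -> FeatureMatrix:
    """Assemble the normalized feature matrix for clustering.

    Each intensity channel is linearly scaled to zero mean and unit
    variance over the retained pixels. Pixels whose SNR_Pyr falls below
    ``snr_floor`` are removed (they become background in the habitat
    map); the SNR map used for the floor is ``snr_reference`` if given,
    else the first input map of kind ``SNR_Pyr``, else no floor is
    applied. ``spatial_weight`` appends pixel (row, col) coordinates
    scaled by the weight; 0 disables spatial terms.
    """
    if isinstance(maps, ParameterMap):
        maps = [maps]
    if not 1 <= len(maps) <= 2:
        raise ValueError("build_features takes one or two maps")
    if snr_floor < 0 or spatial_weight < 0:
        raise ValueError("snr_floor and spatial_weight must be >= 0")
    for m in maps:
        if m.shape != roi.shape:
            raise ValueError("map/ROI shape mismatch")

    keep = roi.mask.copy()
    for m in maps:
        keep &= np.isfinite(m.values)
    snr_map = snr_reference
    if snr_map is None:
        snr_map = next((m for m in maps if m.kind == "SNR_Pyr"), None)
    if snr_map is not None:
        if snr_map.shape != roi.shape:
            raise ValueError("SNR reference map/ROI shape mismatch")
        keep &= np.nan_to_num(snr_map.values, nan=-np.inf) >= snr_floor

    idx = np.flatnonzero(keep.ravel())
    if idx.size < k:
        raise DegenerateInputError(
            f"only {idx.size} pixels survive masking/SNR floor; need >= {k}"
        )

    cols, names = [], []
    for m in maps:
        v = m.values.ravel()[idx]
        sd = v.std()
        if sd == 0:
            raise DegenerateInputError(f"channel {m.kind} is constant over the mask")
        cols.append((v - v.mean()) / sd)
        names.append(m.kind)
    n_intensity = len(cols)
    if spatial_weight > 0:
        rr, cc = np.divmod(idx, roi.shape[1])
        cols.append(rr.astype(float) * spatial_weight)
        cols.append(cc.astype(float) * spatial_weight)
        names += ["row", "col"]
    X = np.column_stack(cols)
    return FeatureMatrix(X, names, idx, roi.shape, n_intensity)


# ---------------------------------------------------------------------------
# k-means (Lloyd's algorithm with k-means++ seeding)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy k-means++: sample several D^2-weighted candidates per step and
    keep the one that most reduces the total potential."""
    n = X.shape[0]
    n_candidates = 2 + int(np.log(k)) if k > 1 else 1
    centroids = np.empty((k, X.shape[1]))
    i = int(rng.integers(n))
    centroids[0] = X[i]
    d2 = ((X - centroids[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            cand = rng.integers(n, size=n_candidates)
        else:
            cand = rng.choice(n, size=n_candidates, p=d2 / total)
        pots = [np.minimum(d2, ((X - X[c]) ** 2).sum(axis=1)).sum() for c in cand]
        best = cand[int(np.argmin(pots))]
        centroids[j] = X[best]
        d2 = np.minimum(d2, ((X - X[best]) ** 2).sum(axis=1))
    return centroids


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    return np.maximum(d2, 0.0)


def _lloyd(X, C, max_iter, tol):
    n, k = X.shape[0], C.shape[0]
    history: list[float] = []
    prev = np.inf
    labels = np.zeros(n, dtype=int)
    for it in range(1, max_iter + 1):
        d2 = _sq_dists(X, C)
        labels = d2.argmin(axis=1)
        # empty-cluster repair: reseed on the point farthest from its centroid
        assigned = d2[np.arange(n), labels]
        for j in range(k):
            if not (labels == j).any():
                far = int(np.argmax(assigned))
                labels[far] = j
                assigned[far] = 0.0
        C = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        obj = float(((X - C[labels]) ** 2).sum())
        history.append(obj)
        if prev - obj <= tol * max(abs(prev), 1e-300):
            break
        prev = obj
    return labels, C, history[-1], it, history


def _hartigan_refine(X, labels, C, max_moves=1000):
    """Single-point reassignment steps under the Hartigan–Wong criterion.

    Moving x from cluster a (size n_a) to b improves the objective iff
    n_b/(n_b+1)·||x−c_b||² < n_a/(n_a−1)·||x−c_a||²; such moves escape
    Lloyd fixed points that are not local minima of the partition
    objective. Centroids are recomputed exactly from the labels at every
    step so floating-point drift cannot produce improvement cycles; the
    best strictly improving move is applied until none remains.
    """
    n, k = X.shape[0], C.shape[0]
    moved = False
    for _ in range(max_moves):
        counts = np.bincount(labels, minlength=k).astype(float)
        C = np.vstack([
            X[labels == j].mean(axis=0) if counts[j] > 0 else C[j] for j in range(k)
        ])
        d2 = _sq_dists(X, C)
        own = d2[np.arange(n), labels]
        wss = float(own.sum())
        loss = counts[labels] / np.maximum(counts[labels] - 1, 1) * own
        gain = counts / (counts + 1) * d2
        gain[np.arange(n), labels] = np.inf
        best_target = gain.argmin(axis=1)
        delta = gain[np.arange(n), best_target] - loss
        delta[counts[labels] <= 1] = np.inf  # never empty a cluster
        i = int(np.argmin(delta))
        if not delta[i] < -1e-9 * (1.0 + wss):
            return labels, C, wss, moved
        labels[i] = best_target[i]
        moved = True
    counts = np.bincount(labels, minlength=k).astype(float)
    C = np.vstack([
        X[labels == j].mean(axis=0) if counts[j] > 0 else C[j] for j in range(k)
    ])
    wss = float(((X - C[labels]) ** 2).sum())
    return labels, C, wss, moved


def kmeans(
    features: FeatureMatrix | np.ndarray,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-8,
    seed: int = 0,
) -> KMeansResult:
    """Best-of-``n_restarts`` k-means: greedy k-means++ seeding, Lloyd
    iterations, and Hartigan–Wong single-point refinement.

    The within-cluster sum of squares is non-increasing across
    iterations; the restart with the lowest final objective wins (ties:
    earliest restart). Deterministic under a fixed seed.
    """
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features, float)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points ({n})")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(max(1, n_restarts)):
        C0 = _kmeanspp_init(X, k, rng)
        labels, C, wss, n_iter, hist = _lloyd(X, C0.copy(), max_iter, tol)
        for _round in range(10):  # alternate refinement and Lloyd polish
            labels, C, wss, moved = _hartigan_refine(X, labels, C)
            hist.append(wss)
            if not moved:
                break
            labels, C, wss, it2, hist2 = _lloyd(X, C, max_iter, tol)
            n_iter += it2
            hist.extend(hist2)
        if best is None or wss < best.wss:
            best = KMeansResult(labels, C, wss, n_iter, hist)
    return best


def sort_clusters(
    raw_labels: np.ndarray,
    features: FeatureMatrix,
    slice_id: str | None = None,
) -> HabitatMap:
    """Relabel clusters in ascending order of mean magnitude.

    Magnitude of a pixel is the sum of its normalized intensity channels
    (spatial columns excluded); clusters are permuted — never split or
    merged — so that habitat 1 has the lowest and habitat k the highest
    mean magnitude. Ties break on the smaller original label.
    """
    raw_labels = np.asarray(raw_labels)
    if raw_labels.shape[0] != features.X.shape[0]:
        raise ValueError("labels must align with the feature matrix rows")
    uniq = np.unique(raw_labels)
    magnitude = features.X[:, : features.n_intensity].sum(axis=1)
    stats = np.array([magnitude[raw_labels == u].mean() for u in uniq])
    order = np.argsort(stats, kind="stable")  # stable => ties keep original order
    new_label_of = {int(uniq[o]): rank + 1 for rank, o in enumerate(order)}
    relabelled = np.array([new_label_of[int(u)] for u in raw_labels])
    grid = np.zeros(features.shape, dtype=int)
    grid.ravel()[features.pixel_index] = relabelled
    return HabitatMap(
        grid, k=len(uniq), ordering_stat=stats[order],
        slice_id=slice_id if slice_id is not None else "0",
    )


def cluster_habitats(
    maps: ParameterMap | list[ParameterMap],
    roi: TumourROI,
    k: int = 3,
    snr_floor: float = 5.0,
    spatial_weight: float = 0.0,
    snr_reference: ParameterMap | None = None,
    n_restarts: int = 20,
    seed: int = 0,
) -> HabitatMap:
    """Full habitat extraction: features -> k-means -> magnitude sorting."""
    fm = build_features(maps, roi, snr_floor, spatial_weight, snr_reference, k=k)
    res = kmeans(fm, k=k, n_restarts=n_restarts, seed=seed)
    sid = maps.slice_id if isinstance(maps, ParameterMap) else maps[0].slice_id
    return sort_clusters(res.labels, fm, slice_id=sid)
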