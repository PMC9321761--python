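"""Gray-level denoising and segmentation.

The pore-analysis protocol denoises the reconstruction with a 3D median
filter and thresholds it with an automatic Otsu criterion computed on the
full 3D histogram; the multiphase protocol clusters gray levels with 1-D
k-means and extracts a phase-of-interest mask.

Histograms use native gray levels (256 bins for 8-bit, 65,536 for 16-bit) —
reported thresholds are therefore gray levels of the input, never rebinned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import BinaryVolume, GrayVolume, LabelVolume

__all__ = [
    "SegmentationResult",
    "median_filter_3d",
    "otsu_threshold",
    "kmeans_segment",
    "extract_phase_mask",
]


@dataclass
class SegmentationResult:
    """Labelled classes plus the decision values that produced them.

    For Otsu, ``threshold`` is set and classes are {0: background, 1: object};
    for k-means, ``centroids`` holds the k class centroids sorted ascending
    and class ids follow that order.
    """

    method: str  # "otsu" | "kmeans"
    labels: LabelVolume
    threshold: float | None = None
    centroids: np.ndarray | None = None
    objective_history: list[float] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return int(self.labels.data.max()) + 1


def median_filter_3d(vol: GrayVolume, width: int = 3) -> GrayVolume:
    """Cubic median filter of odd edge ``width`` voxels, reflect-padded borders."""
    width = int(width)
    if width < 1 or width % 2 == 0:
        raise ValueError(f"median width must be odd and positive, got {width}")
    out = ndimage.median_filter(vol.data, size=width, mode="reflect")
    return GrayVolume(out, vol.voxel_size)


def _native_histogram(data: np.ndarray) -> np.ndarray:
    n_levels = 256 if data.dtype == np.uint8 else 65536
    return np.bincount(data.ravel(), minlength=n_levels).astype(np.float64)


def otsu_level(data: np.ndarray) -> int:
    """Otsu threshold on the native-level histogram of a uint8/uint16 array.

    Returns the gray level t maximizing the between-class variance of the
    split {<= t} / {> t}; the lowest maximizer wins on ties.
    """
    hist = _native_histogram(data)
    total = hist.sum()
    levels = np.arange(hist.size, dtype=np.float64)
    w0 = np.cumsum(hist)
    mu_cum = np.cumsum(hist * levels)
    mu_total = mu_cum[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ValueError("constant volume: Otsu threshold undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~valid] = -np.inf
    return int(np.argmax(between))


def otsu_threshold(vol: GrayVolume, polarity: str = "above") -> SegmentationResult:
    """Automatic single Otsu threshold on the full 3D volume histogram.

    ``polarity`` selects which side of the threshold is the object: ``above``
    (bright phase, default) or ``below`` (dark pores in absorption contrast).
    """
    if polarity not in ("above", "below"):
        raise ValueError(f"polarity must be 'above' or 'below', got {polarity!r}")
    t = otsu_level(vol.data)
    obj = vol.data > t if polarity == "above" else vol.data <= t
    labels = LabelVolume(obj.astype(np.int32), vol.voxel_size)
    return SegmentationResult(method="otsu", labels=labels, threshold=float(t))


def kmeans_segment(
    vol: GrayVolume,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> SegmentationResult:
    """1-D k-means (Lloyd) on gray values, computed on the native histogram.

    Initialisation places centroids at evenly spaced quantiles of the gray
    distribution, which makes the result deterministic for fixed data (the
    ``seed`` argument is accepted for interface symmetry with stochastic
    segmenters but does not influence the outcome).  Voxels equidistant from
    two centroids join the lower-centroid class; classes are relabelled by
    ascending centroid.
    """
    del seed  # deterministic quantile init: kept for API symmetry
    k = int(k)
    hist = _native_histogram(vol.data)
    levels = np.flatnonzero(hist).astype(np.float64)
    counts = hist[hist > 0]
    if k < 1 or k > levels.size:
        raise ValueError(
            f"k must be in [1, number of distinct gray levels={levels.size}], got {k}"
        )
    # quantile initialisation on the empirical gray distribution
    cdf = np.cumsum(counts) / counts.sum()
    qs = (np.arange(k) + 0.5) / k
    centroids = levels[np.searchsorted(cdf, qs, side="left")]
    centroids = np.unique(centroids).astype(np.float64)
    while centroids.size < k:  # duplicate quantiles on spiky histograms
        gaps = np.diff(np.concatenate(([levels[0] - 1], centroids)))
        centroids = np.sort(np.append(centroids, centroids[np.argmax(gaps)] - 0.5))

    history: list[float] = []
    assign = np.zeros(levels.size, dtype=np.int64)
    for _ in range(max_iter):
        # distance ties broken toward the lower centroid: argmin takes the
        # first minimum and centroids are kept sorted
        d = np.abs(levels[:, None] - centroids[None, :])
        assign = np.argmin(d, axis=1)
        wcss = float(np.sum(counts * (levels - centroids[assign]) ** 2))
        history.append(wcss)
        new = centroids.copy()
        for j in range(k):
            m = assign == j
            if m.any():
                new[j] = np.average(levels[m], weights=counts[m])
        new = np.sort(new)
        shift = float(np.max(np.abs(new - centroids)))
        centroids = new
        if shift < tol:
            break
    d = np.abs(levels[:, None] - centroids[None, :])
    assign = np.argmin(d, axis=1)
    history.append(float(np.sum(counts * (levels - centroids[assign]) ** 2)))

    lut = np.zeros(hist.size, dtype=np.int32)
    lut[levels.astype(np.int64)] = assign.astype(np.int32)
    labels = LabelVolume(lut[vol.data], vol.voxel_size)
    return SegmentationResult(
        method="kmeans",
        labels=labels,
        centroids=centroids,
        objective_history=history,
    )


def extract_phase_mask(seg: SegmentationResult, class_ids) -> BinaryVolume:
    """Mask of the voxels whose class is in ``class_ids``.

    An empty selection returns an empty (all-background) mask.
    """
    class_ids = sorted(set(int(c) for c in class_ids))
    known = set(range(seg.n_classes))
    unknown = [c for c in class_ids if c not in known]
    if unknown:
        raise ValueError(f"unknown class ids {unknown}; classes are {sorted(known)}")
    mask = np.isin(seg.labels.data, class_ids)
    return BinaryVolume(mask, seg.labels.voxel_size)
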