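"""Probability maps -> instance labels via marker-controlled watershed.

Markers are the h-maxima of the Euclidean distance transform of the
binarized foreground; the watershed floods the negated transform
constrained to the foreground.  Components below ``min_object_area``
are merged into their largest watershed neighbor, or dropped when
isolated.  Binarization uses a ``>= threshold`` tie rule for
bit-reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_maxima
from skimage.segmentation import watershed


@dataclass(frozen=True)
class PostprocessParams:
    prob_threshold: float = 0.5
    min_object_area: int = 20
    marker_h: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")
        if self.marker_h < 0:
            raise ValueError("marker_h must be >= 0")


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground indicator with a >= tie rule at the threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return prob >= threshold


def watershed_split(foreground: np.ndarray,
                    params: PostprocessParams = PostprocessParams()
                    ) -> np.ndarray:
    fg = np.asarray(foreground).astype(bool)
    if not fg.any():
        return np.zeros(fg.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    if params.marker_h > 0:
        peaks = h_maxima(dist, params.marker_h).astype(bool)
    else:
        peaks = (dist == ndi.maximum_filter(dist, size=3)) & fg
    # every foreground component must own >= 1 marker or the watershed
    # would leave it unlabeled; seed orphans at their deepest pixel
    comps, n_comps = ndi.label(fg)
    if n_comps:
        seeded = np.unique(comps[peaks])
        for comp in range(1, n_comps + 1):
            if comp not in seeded:
                region = comps == comp
                idx = np.unravel_index(
                    np.argmax(np.where(region, dist, -1.0)), fg.shape)
                peaks[idx] = True
    markers, _ = ndi.label(peaks)
    labels = watershed(-dist, markers=markers, mask=fg)
    labels = _suppress_small(labels, params.min_object_area)
    return relabel_consecutive(labels)


def segment(prob: np.ndarray, params: PostprocessParams = PostprocessParams()
            ) -> np.ndarray:
    """binarize -> watershed_split; labels consecutive from 1."""
    return watershed_split(binarize(prob, params.prob_threshold), params)


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return lut[labels]


def _suppress_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 0:
        return labels
    labels = labels.copy()
    areas = np.bincount(labels.ravel())
    for small in np.nonzero(areas[1:] < min_area)[0] + 1:
        if areas[small] == 0:
            continue
        region = labels == small
        ring = ndi.binary_dilation(region) & ~region
        neighbors = labels[ring]
        neighbors = neighbors[neighbors > 0]
        if neighbors.size:
            cand = np.unique(neighbors)
            target = int(cand[np.argmax(areas[cand])])  # largest neighbor
            labels[region] = target
            areas[target] += areas[small]
        else:
            labels[region] = 0
        areas[small] = 0
    return labels
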