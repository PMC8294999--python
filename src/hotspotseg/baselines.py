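"""Comparison segmenters: Otsu thresholding and seeded region growing.

Both are classical intensity-based methods used here as benchmarks for
the level-set segmenter.  Otsu picks the threshold maximizing
between-class variance on a 256-bin histogram of the [0, 1] intensity
range; region growing floods outward from seed pixels while the
intensity stays within a tolerance of the (running or frozen) region
reference.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import InputError

N_BINS = 256

_NEIGHBORS_4 = ((-1, 0), (0, -1), (0, 1), (1, 0))
_NEIGHBORS_8 = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
)


@dataclass
class RegionGrowParams:
    """Seeds, intensity tolerance and connectivity for region growing."""

    seeds: list[tuple[int, int]]
    tolerance: float = 0.15
    connectivity: int = 4
    #: accept against the seed's value instead of the running region mean
    frozen_reference: bool = False

    def __post_init__(self) -> None:
        if not self.seeds:
            raise InputError("at least one seed is required")
        if self.tolerance < 0:
            raise InputError("tolerance must be >= 0")
        if self.connectivity not in (4, 8):
            raise InputError("connectivity must be 4 or 8")


def otsu_segment(
    image: np.ndarray, roi: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Between-class-variance thresholding on a 256-bin [0, 1] histogram.

    Returns ``(mask, threshold)`` with ``mask = image > threshold``.  Ties
    between equally good thresholds go to the lowest one.  With ``roi``
    (boolean array) the histogram and the mask are restricted to the ROI.
    """
    image = np.asarray(image, dtype=float)
    values = image[roi] if roi is not None else image.ravel()
    if values.size == 0 or np.unique(values).size < 2:
        raise InputError(
            "Otsu thresholding needs at least two distinct intensity levels"
        )
    counts, edges = np.histogram(values, bins=N_BINS, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]  # class 0 = bins 0..t
    w1 = total - w0
    cum_mean = np.cumsum(counts * centers)
    mu0 = np.divide(cum_mean[:-1], w0, out=np.zeros(N_BINS - 1), where=w0 > 0)
    mu1 = np.divide(
        cum_mean[-1] - cum_mean[:-1], w1, out=np.zeros(N_BINS - 1), where=w1 > 0
    )
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    t = int(np.argmax(sigma_b))  # argmax takes the lowest index on ties
    threshold = float(edges[t + 1])
    mask = image > threshold
    if roi is not None:
        mask &= roi
    return mask, threshold


def otsu_in_box(
    image: np.ndarray,
    support: np.ndarray,
    dilate: int = 10,
) -> tuple[np.ndarray, float]:
    """Otsu restricted to the detector's support dilated by ``dilate`` pixels.

    Whole-spine histograms swamp small lesions; thresholding inside the
    neighborhood of the probability-map support (morphological dilation,
    so disjoint lesions keep separate local context) isolates segmentation
    quality.  Falls back to the whole image when the support is empty.
    """
    support = np.asarray(support, dtype=bool)
    if not support.any():
        return otsu_segment(image)
    yy, xx = np.mgrid[-dilate : dilate + 1, -dilate : dilate + 1]
    selem = yy * yy + xx * xx <= dilate * dilate
    roi = ndimage.binary_dilation(support, structure=selem)
    return otsu_segment(image, roi=roi)


def region_grow(image: np.ndarray, params: RegionGrowParams) -> np.ndarray:
    """Breadth-first region growing; the mask is the union over seeds.

    A pixel joins when |P(pixel) - reference| <= tolerance, where the
    reference is the running mean of the region grown so far (classic) or
    the seed's value in frozen mode.  FIFO queue with a fixed neighbor
    order makes the result deterministic.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    neighbors = _NEIGHBORS_4 if params.connectivity == 4 else _NEIGHBORS_8
    mask = np.zeros((H, W), dtype=bool)
    for seed in params.seeds:
        r0, c0 = int(seed[0]), int(seed[1])
        if not (0 <= r0 < H and 0 <= c0 < W):
            raise InputError(f"seed {seed} is outside the image")
        visited = np.zeros((H, W), dtype=bool)
        visited[r0, c0] = True
        region = np.zeros((H, W), dtype=bool)
        region[r0, c0] = True
        total = image[r0, c0]
        count = 1
        reference = image[r0, c0]
        queue: deque[tuple[int, int]] = deque([(r0, c0)])
        while queue:
            r, c = queue.popleft()
            for dr, dc in neighbors:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < H and 0 <= cc < W) or visited[rr, cc]:
                    continue
                visited[rr, cc] = True
                # 1e-12 absorbs float error in the running-mean accumulation
                if abs(image[rr, cc] - reference) <= params.tolerance + 1e-12:
                    region[rr, cc] = True
                    total += image[rr, cc]
                    count += 1
                    if not params.frozen_reference:
                        reference = total / count
                    queue.append((rr, cc))
        mask |= region
    return mask


def seeds_from_probability_map(
    prob_map: np.ndarray,
    rho: float = 0.5,
    min_area: int = 8,
    image: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """One seed per connected component of {probability > rho}.

    Each component contributes one peak (saturated plateaus would
    otherwise spray many redundant peaks): the brightest *image* pixel in
    the component when ``image`` is given — the natural seed for a bright
    hot spot — else the maximum-probability pixel.  Components smaller
    than ``min_area`` pixels are treated as detector noise.  Gives the
    baseline segmenters the same detection input as the level-set method.
    Falls back to the global probability maximum when nothing qualifies.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    score = prob_map if image is None else np.asarray(image, dtype=float)
    labels, n = ndimage.label(prob_map > rho)
    seeds: list[tuple[int, int]] = []
    for lbl in range(1, n + 1):
        comp = labels == lbl
        if int(comp.sum()) < min_area:
            continue
        masked = np.where(comp, score, -np.inf)
        r, c = np.unravel_index(np.argmax(masked), prob_map.shape)
        seeds.append((int(r), int(c)))
    if not seeds:
        r, c = np.unravel_index(np.argmax(prob_map), prob_map.shape)
        seeds = [(int(r), int(c))]
    return seeds
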