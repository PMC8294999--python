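"""Synthetic spine-MRI-like phantom slices with planted hot spots.

Real T2-weighted spinal series show an alternating vertebra/disc banding,
a smooth coil-sensitivity bias field, noise, and — in metastatic disease —
focal bright lesions ("hot spots").  The generator reproduces those four
ingredients on a small 2-D grid together with exact ground-truth masks and
a three-level gold label per slice:

* level I   — hot spots certainly present (high-contrast lesions),
* level II  — uncertain (lesion contrast drawn just above the noise floor),
* level III — no hot spot (no lesion planted).

Every draw is taken from a :class:`numpy.random.Generator` seeded
explicitly, so identical ``(spec, seed)`` pairs are bit-identical.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import SpecificationError

LEVEL_I = "I"
LEVEL_II = "II"
LEVEL_III = "III"

#: Gaussian sigma (pixels) used to soften lesion edges — emulates the
#: partial-volume blur at lesion boundaries on real MRI.
EDGE_SIGMA = 0.8

#: Peak amplitude of the smooth multiplicative-style bias field.
BIAS_AMPLITUDE = 0.03

#: Half-amplitude of the vertebra/disc intensity banding.  Kept below the
#: level where the banding itself would dominate a two-phase piecewise-
#: constant fit of the slice: with lesion contrast c and band half-
#: amplitude a, the lesion is the optimal second phase only while the
#: band sum of squares (~2*N_bg*a^2) stays under the lesion residual
#: (~N_les*(c-a)^2); for the default cohort that requires a < ~0.05.
BAND_AMPLITUDE = 0.05


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic slice.

    Parameters
    ----------
    height, width : int
        Image size in pixels.
    n_hotspots : int
        Number of planted lesions (0 gives a level-III slice).
    hotspot_radius_range : (float, float)
        Min/max lesion radius in pixels.
    hotspot_contrast : float
        Additive lesion intensity on the [0, 1] scale.
    background_bands : int
        Number of vertebra/disc-like horizontal intensity bands.
    noise_sigma : float
        Standard deviation of the additive Gaussian noise.
    ambiguous : bool
        If True the planted lesions use a low contrast drawn just above
        the noise floor (level-II construction); ``hotspot_contrast`` is
        then ignored for the planted lesions.
    """

    height: int = 128
    width: int = 128
    n_hotspots: int = 2
    hotspot_radius_range: tuple[float, float] = (4.0, 9.0)
    hotspot_contrast: float = 0.35
    background_bands: int = 5
    noise_sigma: float = 0.08
    ambiguous: bool = False

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise SpecificationError("height/width must be at least 16 pixels")
        if self.n_hotspots < 0:
            raise SpecificationError("n_hotspots must be >= 0")
        rmin, rmax = self.hotspot_radius_range
        if rmin > rmax or rmin <= 0:
            raise SpecificationError(
                "hotspot_radius_range must satisfy 0 < min <= max"
            )
        if self.noise_sigma < 0:
            raise SpecificationError("noise_sigma must be >= 0")
        if self.n_hotspots > 0 and self.hotspot_contrast <= 0 and not self.ambiguous:
            raise SpecificationError(
                "hotspot_contrast must be > 0 when n_hotspots > 0"
            )
        if self.background_bands < 1:
            raise SpecificationError("background_bands must be >= 1")


@dataclass(frozen=True)
class PhantomCase:
    """One generated slice: image, ground-truth mask, gold label, seed."""

    image: np.ndarray
    mask: np.ndarray
    gold_label: str
    seed: int

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise SpecificationError("mask dimensions must equal image dimensions")
        nonempty = bool(self.mask.any())
        if nonempty != (self.gold_label in (LEVEL_I, LEVEL_II)):
            raise SpecificationError(
                "mask must be nonempty iff gold_label is I or II"
            )


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Banded background plus a smooth low-frequency bias field, ~[0.3, 0.46]."""
    rows = np.arange(spec.height, dtype=float)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    bands = 0.375 + BAND_AMPLITUDE * np.sin(
        2.0 * math.pi * spec.background_bands * rows / spec.height + phase
    )
    bg = np.repeat(bands[:, None], spec.width, axis=1)
    # Bias field: a coarse random grid upsampled to image size.
    coarse = rng.normal(0.0, 1.0, size=(4, 4))
    zoom = (spec.height / 4.0, spec.width / 4.0)
    field = ndimage.zoom(coarse, zoom, order=3, mode="nearest")[
        : spec.height, : spec.width
    ]
    peak = np.abs(field).max()
    if peak > 0:
        field = field / peak * BIAS_AMPLITUDE
    return bg + field


def _place_lesions(
    spec: PhantomSpec, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Draw non-overlapping lesion centers/radii by rejection sampling."""
    rmin, rmax = spec.hotspot_radius_range
    lesions: list[tuple[float, float, float]] = []
    for _ in range(spec.n_hotspots):
        placed = False
        for _attempt in range(500):
            r = rng.uniform(rmin, rmax)
            cy = rng.uniform(r + 2, spec.height - r - 2)
            cx = rng.uniform(r + 2, spec.width - r - 2)
            if all(
                math.hypot(cy - oy, cx - ox) >= r + orad + 3.0
                for oy, ox, orad in lesions
            ):
                lesions.append((cy, cx, r))
                placed = True
                break
        if not placed:
            raise SpecificationError(
                "could not place non-overlapping hot spots; reduce n_hotspots "
                "or radii for this image size"
            )
    return lesions


def _ambiguous_contrast(spec: PhantomSpec, rng: np.random.Generator) -> float:
    # Just above the noise floor so a triage classifier is genuinely unsure.
    lo = max(2.0 * spec.noise_sigma, 0.05)
    hi = max(3.0 * spec.noise_sigma, 0.06)
    return float(rng.uniform(lo, hi))


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Generate one synthetic slice with its ground-truth mask.

    The image is ``clip(background + smoothed lesion profile + noise, 0, 1)``;
    the mask is the exact union of the planted disks (before edge smoothing).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    image = _background(spec, rng)
    mask = np.zeros((spec.height, spec.width), dtype=bool)

    lesions = _place_lesions(spec, rng)
    if lesions:
        contrast = (
            _ambiguous_contrast(spec, rng)
            if spec.ambiguous
            else spec.hotspot_contrast
        )
        yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
        profile = np.zeros_like(image)
        for cy, cx, r in lesions:
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            mask |= disk
            profile[disk] = contrast
        profile = ndimage.gaussian_filter(profile, EDGE_SIGMA)
        image = image + profile

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    if spec.n_hotspots == 0:
        label = LEVEL_III
    elif spec.ambiguous:
        label = LEVEL_II
    else:
        label = LEVEL_I
    return PhantomCase(image=image, mask=mask, gold_label=label, seed=int(seed))


def generate_cohort(
    counts_by_level: tuple[int, int, int],
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
) -> list[PhantomCase]:
    """Generate a labelled cohort with the requested level histogram.

    Level-I cases use ``base_spec`` as-is (forcing at least one lesion),
    level-II cases use the ambiguous low-contrast variant, level-III cases
    plant no lesion.  Case order is shuffled deterministically.
    """
    n1, n2, n3 = counts_by_level
    if min(n1, n2, n3) < 0:
        raise SpecificationError("cohort counts must be >= 0")
    base = base_spec or PhantomSpec()
    base.validate()

    spec_i = dataclasses.replace(
        base, n_hotspots=max(base.n_hotspots, 1), ambiguous=False
    )
    spec_ii = dataclasses.replace(
        base, n_hotspots=max(base.n_hotspots, 1), ambiguous=True
    )
    spec_iii = dataclasses.replace(base, n_hotspots=0, ambiguous=False)

    ss = np.random.SeedSequence(seed)
    total = n1 + n2 + n3
    child_seeds = [int(s) for s in ss.generate_state(total + 1)]
    specs = [spec_i] * n1 + [spec_ii] * n2 + [spec_iii] * n3
    cases = [generate_phantom(sp, sd) for sp, sd in zip(specs, child_seeds)]
    order_rng = np.random.default_rng(child_seeds[-1] if cases else 0)
    order = order_rng.permutation(total)
    return [cases[i] for i in order]
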