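"""Binarization of the structure channel within the cytosol.

The primary mode is a locally adaptive threshold computed from cytosol-masked
window statistics: a pixel is foreground iff its intensity exceeds the local
mean plus ``sensitivity`` local standard deviations, where both statistics are
computed over cytosolic pixels only (masked normalized convolution).  Because
the rule is local and affine-equivariant in intensity, it is unbiased by the
overall abundance of structure and by global brightness: cells with sparse
and dense tubule networks are thresholded by the same per-pixel criterion.

Fallbacks: a global mean-fluorescence threshold and acceptance of
pre-binarized images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import remove_small_objects

from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ThresholdSettings:
    """Binarization parameters.

    Parameters
    ----------
    mode : {"adaptive", "mean", "prebinarized"}
    window_um : float
        Side length of the square local window, µm; converted to an odd pixel
        count of at least 3.  Default 3 µm, roughly 1.5x the sarcomere
        spacing, so each window sees local background between tubules.
    sensitivity : float
        Offset scale ``s`` >= 0; foreground iff I > local_mean + s * local_sd.
    k_mean : float
        Multiplier for the global-mean mode: foreground iff I > k * cytosol mean.
    min_object : int
        Minimum connected-component size in pixels (despeckling).
    noise_floor_k : float
        Minimum contrast requirement in units of the image noise scale: a
        foreground pixel must also exceed the local mean by ``noise_floor_k``
        noise standard deviations, where the noise scale is the MAD-based SD
        of cytosolic intensities.  In windows containing structure the local
        SD dominates and the floor is inactive; in structure-free windows the
        local SD collapses to the noise SD and ``mean + s*sd`` would flag the
        upper tail of the noise, which the floor suppresses.  The floor is
        affine-equivariant, so intensity-scale invariance is preserved
        exactly.  Set 0 to disable.
    """

    mode: str = "adaptive"
    window_um: float = 3.0
    sensitivity: float = 1.0
    k_mean: float = 1.0
    min_object: int = 4
    noise_floor_k: float = 4.0

    def __post_init__(self) -> None:
        if self.mode not in ("adaptive", "mean", "prebinarized"):
            raise ValidationError(f"unknown threshold mode {self.mode!r}")
        if self.sensitivity < 0:
            raise ValidationError("sensitivity must be >= 0")
        if self.min_object < 0:
            raise ValidationError("min_object must be >= 0")

    def window_pixels(self, voxel_size: tuple[float, float, float]) -> int:
        dx, dy, _ = voxel_size
        w = int(round(self.window_um / ((dx + dy) / 2.0)))
        w = max(3, w)
        if w % 2 == 0:
            w += 1
        return w


@dataclass
class StructureMap:
    """Binary map of detected structure, restricted to a cytosolic domain.

    ``mask`` and ``domain`` are (z, y, x) stacks (depth 1 for single planes);
    mask ⊆ domain always holds.
    """

    mask: np.ndarray
    domain: np.ndarray
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = _as_stack(self.mask)
        self.domain = _as_stack(self.domain)
        if self.mask.shape != self.domain.shape:
            raise ValidationError("mask and domain shapes differ")
        if np.any(self.mask & ~self.domain):
            raise ValidationError("structure mask leaves the cytosolic domain")


def _as_stack(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=bool)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValidationError(f"mask must be 2D or 3D, got ndim={arr.ndim}")
    return arr


def _masked_local_stats(plane: np.ndarray, domain: np.ndarray, window: int):
    """Local mean and sd over ``window``-sided squares, using domain pixels only."""
    d = domain.astype(float)
    i1 = ndimage.uniform_filter(plane * d, size=window, mode="constant")
    i2 = ndimage.uniform_filter(plane * plane * d, size=window, mode="constant")
    cnt = ndimage.uniform_filter(d, size=window, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = i1 / cnt
        var = i2 / cnt - mu * mu
    var = np.clip(var, 0.0, None)
    return mu, np.sqrt(var)


def adaptive_binarize(
    image: np.ndarray,
    cytosol: np.ndarray,
    settings: ThresholdSettings,
    voxel_size: tuple[float, float, float],
) -> StructureMap:
    """Adaptive local thresholding over the cytosolic compartment.

    Statistics exclude pixels outside the cytosol, so the dark exterior and
    the bright membrane band never bias local thresholds near the cell
    border.  Stacks are thresholded per z-slice.  Ties at the threshold are
    background (strict inequality), so constant regions stay empty.
    """
    img = np.asarray(image, dtype=float)
    stack = _as_stack(cytosol)
    if img.ndim == 2:
        img = img[np.newaxis]
    if img.shape != stack.shape:
        raise ValidationError("image and cytosol shapes differ")
    window = settings.window_pixels(voxel_size)
    flags: list[str] = []
    out = np.zeros_like(stack)
    for z in range(stack.shape[0]):
        dom = stack[z]
        if not dom.any():
            continue
        ys, xs = np.nonzero(dom)
        if window > (ys.max() - ys.min() + 1) and window > (xs.max() - xs.min() + 1):
            raise ValidationError(
                f"local window ({window} px) exceeds the cytosol extent; "
                "use a smaller window"
            )
        vals = img[z][dom]
        if vals.max() == vals.min():
            flags.append(f"z{z}:zero-variance cytosol, empty map")
            logger.warning("slice %d: zero-variance cytosol; no structure detected", z)
            continue
        mu, sd = _masked_local_stats(img[z], dom, window)
        fg = dom & (img[z] > mu + settings.sensitivity * sd)
        if settings.noise_floor_k > 0:
            med = np.median(vals)
            sigma_n = 1.4826 * np.median(np.abs(vals - med))
            fg &= img[z] > mu + settings.noise_floor_k * sigma_n
        out[z] = fg
    out = _despeckle(out, settings.min_object)
    return StructureMap(mask=out, domain=stack, flags=flags)


def _despeckle(mask: np.ndarray, min_object: int) -> np.ndarray:
    if min_object <= 1:
        return mask
    out = np.zeros_like(mask)
    for z in range(mask.shape[0]):
        if mask[z].any():
            out[z] = remove_small_objects(mask[z], max_size=min_object - 1)
    return out


def mean_binarize(
    image: np.ndarray, cytosol: np.ndarray, settings: ThresholdSettings
) -> StructureMap:
    """Global threshold at ``k_mean`` times the mean cytosolic fluorescence."""
    if settings.k_mean <= 0:
        raise ValidationError("k_mean must be > 0")
    img = np.asarray(image, dtype=float)
    stack = _as_stack(cytosol)
    if img.ndim == 2:
        img = img[np.newaxis]
    mean = img[stack].mean()
    mask = stack & (img > settings.k_mean * mean)
    mask = _despeckle(mask, settings.min_object)
    return StructureMap(mask=mask, domain=stack)


def accept_prebinarized(image: np.ndarray, cytosol: np.ndarray) -> StructureMap:
    """Accept an externally binarized image: nonzero = structure, within cytosol."""
    img = np.asarray(image)
    stack = _as_stack(cytosol)
    if img.ndim == 2:
        img = img[np.newaxis]
    values = np.unique(img)
    if len(values) > 2:
        raise ValidationError(
            f"image is not binary: {len(values)} distinct intensity values"
        )
    mask = (img != 0) & stack
    return StructureMap(mask=mask, domain=stack)


def binarize(
    image: np.ndarray,
    cytosol: np.ndarray,
    settings: ThresholdSettings,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> StructureMap:
    """Dispatch on ``settings.mode``."""
    if settings.mode == "adaptive":
        return adaptive_binarize(image, cytosol, settings, voxel_size)
    if settings.mode == "mean":
        return mean_binarize(image, cytosol, settings)
    return accept_prebinarized(image, cytosol)


def compute_density(sm: StructureMap) -> float:
    """Fraction of the cytosolic domain covered by structure, pooled over slices.

    Density is measured on the binarized map, before skeletonization, so
    changes in tubule diameter are reflected in the value.
    """
    n_dom = int(np.count_nonzero(sm.domain))
    if n_dom == 0:
        raise ValidationError("empty cytosolic domain")
    return int(np.count_nonzero(sm.mask)) / n_dom
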