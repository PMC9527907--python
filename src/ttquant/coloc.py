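"""Binary co-localization between two channels' structures.

Overlap is quantified Manders-style on binary masks: the fraction of A's
pixels that fall within a dilation of B (and vice versa), with the dilation
radius acting as a registration/chromatic-shift tolerance.  The same pair of
fractions is computed restricted to the transverse-only and
longitudinal-only skeleton subsets, so co-localization can be assessed
separately for the two orientations.  Fractions with an empty reference set
are reported as NaN (flagged), never 0: "no structure" is distinct from "no
overlap".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation, disk

from .binarization import _as_stack
from .skeleton import LONGITUDINAL, TRANSVERSE, OrientedSkeleton
from .types import ValidationError


@dataclass
class ColocResult:
    frac_A_in_B: float
    frac_B_in_A: float
    per_orientation: dict[str, tuple[float, float]] = field(default_factory=dict)
    tolerance: int = 0
    flags: list[str] = field(default_factory=list)


def _dilate(mask: np.ndarray, tolerance: int) -> np.ndarray:
    if tolerance <= 0:
        return mask
    selem = disk(tolerance)
    out = np.zeros_like(mask)
    for z in range(mask.shape[0]):
        if mask[z].any():
            out[z] = dilation(mask[z], selem)
    return out


def coloc_fractions(
    A: np.ndarray, B: np.ndarray, tolerance: int = 0
) -> tuple[float, float]:
    """Overlap fractions ``(|A ∩ dilate(B)| / |A|, |B ∩ dilate(A)| / |B|)``.

    Empty A (or B) yields NaN for the corresponding fraction.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    a = _as_stack(A)
    b = _as_stack(B)
    if a.shape != b.shape:
        raise ValidationError("masks are on different grids")
    nA = int(np.count_nonzero(a))
    nB = int(np.count_nonzero(b))
    fAB = float(np.count_nonzero(a & _dilate(b, tolerance)) / nA) if nA else float("nan")
    fBA = float(np.count_nonzero(b & _dilate(a, tolerance)) / nB) if nB else float("nan")
    return fAB, fBA


def coloc_by_orientation(
    osA: OrientedSkeleton, osB: OrientedSkeleton, tolerance: int = 1
) -> ColocResult:
    """Overall and per-orientation overlap between two oriented skeletons.

    Both skeletons must come from the same aligned cell; the transverse
    (resp. longitudinal) fractions compare only the pixels so labelled in
    each channel.
    """
    if osA.skeleton.shape != osB.skeleton.shape:
        raise ValidationError("skeletons are on different grids")
    flags: list[str] = []
    fAB, fBA = coloc_fractions(osA.skeleton, osB.skeleton, tolerance)
    per: dict[str, tuple[float, float]] = {}
    for name, code in (("transverse", TRANSVERSE), ("longitudinal", LONGITUDINAL)):
        a = osA.oriented(code)
        b = osB.oriented(code)
        f1, f2 = coloc_fractions(a, b, tolerance)
        if not a.any():
            flags.append(f"channel A has no {name} skeleton")
        if not b.any():
            flags.append(f"channel B has no {name} skeleton")
        per[name] = (f1, f2)
    if not osA.skeleton.any():
        flags.append("channel A skeleton empty")
    if not osB.skeleton.any():
        flags.append("channel B skeleton empty")
    return ColocResult(
        frac_A_in_B=fAB, frac_B_in_A=fBA, per_orientation=per,
        tolerance=tolerance, flags=flags,
    )


def overlay_rgb(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Colour-coded overlay: A-only red, B-only green, overlap yellow (uint8 RGB)."""
    a = _as_stack(A)
    b = _as_stack(B)
    rgb = np.zeros(a.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.where(a, 255, 0)
    rgb[..., 1] = np.where(b, 255, 0)
    return rgb
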