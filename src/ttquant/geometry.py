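"""Cell alignment and mask construction.

A cardiomyocyte is analysed in a standard frame: the manually indicated long
axis is rotated horizontal, the frame is trimmed to the outline bounding box,
the rough outline is refined to the exact border by a region-based active
contour, and the refined cell mask is split into a sarcolemmal (membrane
band) and a cytosolic compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask
from skimage.segmentation import morphological_chan_vese

from .types import CellAnnotation, ImageVolume, TTQuantError, ValidationError

logger = logging.getLogger(__name__)


class SegmentationError(TTQuantError):
    """Active contour collapsed or produced no cell."""


def _rot_matrix(beta_deg: float) -> np.ndarray:
    """Rotation acting on (y, x) coordinate vectors.

    A vector at angle ``phi = atan2(dy, dx)`` is moved to angle ``phi + beta``.
    """
    b = np.deg2rad(beta_deg)
    return np.array([[np.cos(b), np.sin(b)], [-np.sin(b), np.cos(b)]])


@dataclass
class AlignmentTransform:
    """Rigid in-plane transform bringing the cell long axis horizontal.

    ``rotation_angle`` is in degrees; points map as
    ``q = R(rotation_angle) @ (p - center_in) + shift - crop_origin`` in
    (y, x) coordinates.
    """

    rotation_angle: float
    center_in: np.ndarray  # rotation centre in input coords (y, x)
    shift: np.ndarray  # translation placing the rotated canvas at origin
    crop_box: tuple[int, int, int, int]  # (y0, y1, x0, x1), half-open
    input_shape: tuple[int, int]

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        R = _rot_matrix(self.rotation_angle)
        q = (R @ (pts - self.center_in).T).T + self.shift
        y0, _, x0, _ = self.crop_box
        return q - np.array([y0, x0])

    def invert_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        y0, _, x0, _ = self.crop_box
        R = _rot_matrix(-self.rotation_angle)
        return (R @ (pts + np.array([y0, x0]) - self.shift).T).T + self.center_in

    def apply_plane(self, plane: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample one 2D plane into the aligned, cropped frame."""
        y0, y1, x0, x1 = self.crop_box
        out_shape = (y1 - y0, x1 - x0)
        if abs(self.rotation_angle) < 1e-12:
            # pure crop fast path (with zero padding if the box leaves the image)
            return _crop_pad(plane, self.crop_box)
        Rinv = _rot_matrix(-self.rotation_angle)
        offset = self.center_in - Rinv @ (self.shift - np.array([y0, x0]))
        return ndimage.affine_transform(
            np.asarray(plane, dtype=float),
            Rinv,
            offset=offset,
            output_shape=out_shape,
            order=order,
            mode="constant",
            cval=0.0,
        )

    def invert_plane(self, plane: np.ndarray, order: int = 0) -> np.ndarray:
        """Map an aligned-frame plane (e.g. a mask) back onto the input grid."""
        y0, _, x0, _ = self.crop_box
        R = _rot_matrix(self.rotation_angle)
        # inverse of apply_plane: input coords -> aligned coords
        offset = self.shift - np.array([y0, x0]) - R @ self.center_in
        return ndimage.affine_transform(
            np.asarray(plane, dtype=float),
            R,
            offset=offset,
            output_shape=self.input_shape,
            order=order,
            mode="constant",
            cval=0.0,
        )


def _crop_pad(plane: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    y0, y1, x0, x1 = box
    out = np.zeros((y1 - y0, x1 - x0), dtype=float)
    sy0, sy1 = max(y0, 0), min(y1, plane.shape[0])
    sx0, sx1 = max(x0, 0), min(x1, plane.shape[1])
    if sy1 > sy0 and sx1 > sx0:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = plane[sy0:sy1, sx0:sx1]
    return out


def axis_angle(ann: CellAnnotation) -> float:
    """Angle (degrees) of the annotated long axis relative to horizontal, in (-90, 90]."""
    dy, dx = ann.axis[1] - ann.axis[0]
    phi = np.degrees(np.arctan2(dy, dx))
    while phi > 90:
        phi -= 180
    while phi <= -90:
        phi += 180
    return phi


def align_cell(
    image: ImageVolume,
    ann: CellAnnotation,
    margin: int = 10,
    order: int = 1,
) -> tuple[ImageVolume, AlignmentTransform, CellAnnotation]:
    """Rotate the cell so its long axis is horizontal and trim to the outline.

    The rotation is strictly in-plane and shared by every slice of a stack;
    of the two 180°-equivalent solutions the one with the smaller absolute
    angle is used.  The crop box is the transformed outline's bounding box
    padded by ``margin`` pixels.
    """
    phi = axis_angle(ann)
    beta = -phi  # rotate so the axis angle becomes zero
    H, W = image.shape_yx
    center = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    R = _rot_matrix(beta)
    corners = np.array([[0, 0], [0, W - 1], [H - 1, 0], [H - 1, W - 1]], dtype=float)
    rc = (R @ (corners - center).T).T
    shift = -rc.min(axis=0)

    tf_partial = AlignmentTransform(
        rotation_angle=beta,
        center_in=center,
        shift=shift,
        crop_box=(0, 0, 0, 0),
        input_shape=(H, W),
    )
    # transformed outline in full rotated-canvas coordinates
    R_out = (R @ (np.asarray(ann.outline) - center).T).T + shift
    y0 = int(np.floor(R_out[:, 0].min())) - margin
    y1 = int(np.ceil(R_out[:, 0].max())) + margin + 1
    x0 = int(np.floor(R_out[:, 1].min())) - margin
    x1 = int(np.ceil(R_out[:, 1].max())) + margin + 1
    canvas_h = int(np.ceil(rc[:, 0].max() - rc[:, 0].min())) + 1
    canvas_w = int(np.ceil(rc[:, 1].max() - rc[:, 1].min())) + 1
    if y0 < 0 or x0 < 0 or y1 > canvas_h or x1 > canvas_w:
        logger.info("cell %s: outline near image edge; padding with zeros", ann.cell_id)
    tf = AlignmentTransform(
        rotation_angle=beta,
        center_in=center,
        shift=shift,
        crop_box=(y0, y1, x0, x1),
        input_shape=(H, W),
    )

    aligned = np.empty(
        (image.n_channels, image.depth, y1 - y0, x1 - x0), dtype=np.float64
    )
    for c in range(image.n_channels):
        for z in range(image.depth):
            aligned[c, z] = tf.apply_plane(image.data[c, z], order=order)
    aligned = np.clip(aligned, 0, None)
    out_vol = ImageVolume(aligned, image.voxel_size, image.bit_depth)
    out_ann = CellAnnotation(
        cell_id=ann.cell_id,
        axis=tf.apply_points(ann.axis),
        outline=tf.apply_points(ann.outline),
    )
    return out_vol, tf, out_ann


def _reset_chan_vese_smoothing() -> None:
    """Give every segmentation the same smoothing-operator phase.

    The morphological curvature operator alternates between its two
    compositions via module-global state, so without a reset the result of a
    segmentation would depend on how many smoothing steps earlier calls in
    the same process happened to run.
    """
    try:
        from skimage.segmentation import morphsnakes as ms

        ms._curvop = ms._fcycle(
            [lambda u: ms.sup_inf(ms.inf_sup(u)), lambda u: ms.inf_sup(ms.sup_inf(u))]
        )
    except (ImportError, AttributeError):  # pragma: no cover - library internals moved
        pass


def rasterize_outline(outline: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed (y, x) polygon: pixels whose centres fall inside."""
    return polygon2mask(shape, np.asarray(outline, dtype=float))


def segment_cell(
    plane: np.ndarray,
    outline: np.ndarray,
    max_iter: int = 500,
    tol: int = 0,
    patience: int = 5,
    smoothing: int = 1,
    lambda1: float = 1.0,
    lambda2: float = 1.0,
    cell_id: str = "?",
) -> np.ndarray:
    """Refine a rough outline into an exact cell mask with a Chan-Vese contour.

    The region-based energy is initialised from the rasterized rough outline
    and iterated until the mask changes by at most ``tol`` pixels over
    ``patience`` consecutive iterations, or ``max_iter``.  On noisy images
    the discrete flow settles into a period-2 limit cycle of boundary pixels
    rather than a fixed point, so stability is assessed against the state
    two iterations back, which treats such cycles as converged.  The largest
    connected component is kept and holes are filled.

    Parameters
    ----------
    plane : 2D array
        The membrane/structure channel (max-projected for stacks).
    outline : (n, 2) array of (y, x)
        Rough outline enclosing most of the cell.
    """
    _reset_chan_vese_smoothing()
    plane = np.asarray(plane, dtype=float)
    init = rasterize_outline(outline, plane.shape)
    if not init.any():
        raise SegmentationError(f"cell {cell_id}: rough outline rasterizes to nothing")
    if plane.max() == plane.min():
        raise SegmentationError(f"cell {cell_id}: no intensity contrast; contour collapsed")

    state = {
        "prev": init.astype(bool), "prev2": init.astype(bool),
        "stable": 0, "iters": 0, "done": False,
    }

    def _callback(ls: np.ndarray) -> None:
        cur = ls.astype(bool)
        changed = min(
            int(np.count_nonzero(cur ^ state["prev"])),
            int(np.count_nonzero(cur ^ state["prev2"])),
        )
        state["prev2"] = state["prev"]
        state["prev"] = cur
        state["iters"] += 1
        state["stable"] = state["stable"] + 1 if changed <= tol else 0
        if state["stable"] >= patience:
            state["done"] = True

    # chunked iteration so convergence can stop early
    ls = init
    chunk = 25
    while state["iters"] < max_iter and not state["done"]:
        n = min(chunk, max_iter - state["iters"])
        ls = morphological_chan_vese(
            plane,
            num_iter=n,
            init_level_set=ls,
            smoothing=smoothing,
            lambda1=lambda1,
            lambda2=lambda2,
            iter_callback=_callback,
        )
        if state["done"]:
            break
    if not state["done"]:
        logger.warning("cell %s: active contour did not converge in %d iterations",
                       cell_id, max_iter)
    mask = ls.astype(bool)
    if not mask.any():
        raise SegmentationError(f"cell {cell_id}: active contour collapsed to empty mask")
    # keep foreground as the brighter phase
    fg_mean = plane[mask].mean()
    bg = ~mask
    if bg.any() and plane[bg].mean() > fg_mean:
        mask = bg
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        raise SegmentationError(f"cell {cell_id}: empty segmentation result")
    return mask


@dataclass
class CellMasks:
    """Whole-cell, sarcolemmal-band and cytosolic masks on the aligned grid.

    Invariant (by construction): membrane and cytosol partition the cell.
    """

    cell: np.ndarray
    membrane: np.ndarray
    cytosol: np.ndarray


def build_masks(cell_mask: np.ndarray, w_mem: int) -> CellMasks:
    """Split a cell mask into a membrane band of width ``w_mem`` and the cytosol.

    The membrane band is the set difference between the cell and the cell
    eroded ``w_mem`` times with the 4-connected unit cross.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    if not cell.any():
        raise ValidationError("cell mask is empty")
    if w_mem < 1:
        raise ValidationError("membrane width must be >= 1 pixel")
    cross = ndimage.generate_binary_structure(2, 1)
    cytosol = ndimage.binary_erosion(cell, structure=cross, iterations=w_mem)
    if not cytosol.any():
        raise ValidationError(
            f"cell too thin: erosion by membrane width {w_mem} px empties the cell"
        )
    membrane = cell & ~cytosol
    return CellMasks(cell=cell, membrane=membrane, cytosol=cytosol)


def membrane_width_pixels(w_mem_um: float, voxel_size: tuple[float, float, float]) -> int:
    """Convert a membrane band width in µm to pixels (at least 1)."""
    dx, dy, _ = voxel_size
    return max(1, int(round(w_mem_um / ((dx + dy) / 2.0))))
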