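"""Reading and writing of on-disk artifacts.

Images are TIFF (single- or multi-page, 8/16-bit, OME metadata honoured when
present); annotations are JSON sidecar files; metrics are a tab-separated
table with a stable column order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import CellAnnotation, ImageVolume, MetricsReport, ValidationError

METRICS_COLUMNS = [
    "cell_id",
    "mode",
    "density_raw",
    "density_skeleton",
    "fraction_transverse",
    "fraction_longitudinal",
    "fraction_ambiguous",
    "distance_mean_um",
    "distance_median_um",
    "distance_max_um",
    "distance_sd_um",
    "flags",
]


def _axes_to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand a tifffile array with axis string ``axes`` to (C, Z, Y, X)."""
    axes = axes.upper().replace("S", "C")  # sample axis treated as channels
    if "Q" in axes:  # unknown axis: treat a single unknown leading axis as Z
        axes = axes.replace("Q", "Z", 1)
    for ax in axes:
        if ax not in "CZYXTI":
            raise ValidationError(f"unsupported TIFF axis {ax!r} (axes={axes})")
    if "T" in axes or "I" in axes:
        # a time/sequence axis of length 1 can be squeezed; anything else is unsupported
        for ax in ("T", "I"):
            while ax in axes:
                i = axes.index(ax)
                if data.shape[i] != 1:
                    raise ValidationError("time-series TIFFs are not supported")
                data = np.squeeze(data, axis=i)
                axes = axes[:i] + axes[i + 1 :]
    for ax in "CZ":
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "CZYX"]
    return np.transpose(data, order)


def _voxel_size_from_tiff(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (dx, dy, dz) in µm from OME or ImageJ metadata, if present."""
    if tif.ome_metadata:
        try:
            from xml.etree import ElementTree

            root = ElementTree.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None:
                dx = px.get("PhysicalSizeX")
                dy = px.get("PhysicalSizeY")
                dz = px.get("PhysicalSizeZ")
                if dx and dy:
                    return float(dx), float(dy), float(dz) if dz else float(dx)
        except Exception:
            pass
    return None


def read_image(path: str | Path, voxel_size: tuple[float, float, float] | None = None) -> ImageVolume:
    """Read a TIFF into an :class:`ImageVolume` with axes (channel, z, y, x).

    Parameters
    ----------
    path : path
        Single- or multi-page TIFF, 8- or 16-bit, 1-4 channels.
    voxel_size : (dx, dy, dz) in µm, optional
        Override for files without physical-size metadata.  Required when the
        file carries none: physical units are never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        meta_voxel = _voxel_size_from_tiff(tif)
    if data.dtype.kind not in "ui" or data.dtype.itemsize > 2:
        if data.dtype.kind != "f":
            raise ValidationError(f"unsupported bit depth/dtype: {data.dtype}")
    bit_depth = 8 * data.dtype.itemsize if data.dtype.kind in "ui" else 32
    data = _axes_to_czyx(np.asarray(data), axes)
    vs = voxel_size or meta_voxel
    if vs is None:
        raise ValidationError(
            f"{path}: no voxel size in metadata and no override given; "
            "physical units are required"
        )
    return ImageVolume(data=data.astype(np.float64), voxel_size=tuple(vs), bit_depth=bit_depth)


def write_image(
    volume: ImageVolume, path: str | Path, dtype: np.dtype | type = np.uint16
) -> None:
    """Write an :class:`ImageVolume` as an OME-TIFF with physical-size metadata."""
    dx, dy, dz = volume.voxel_size
    data = volume.data
    if np.issubdtype(np.dtype(dtype), np.integer):
        data = np.clip(np.rint(data), 0, np.iinfo(dtype).max)
    tifffile.imwrite(
        Path(path),
        data.astype(dtype),
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": dx,
            "PhysicalSizeY": dy,
            "PhysicalSizeZ": dz,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZUnit": "µm",
        },
    )


def write_mask_tiff(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask (2D or 3D) as an 8-bit 0/255 TIFF."""
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    tifffile.imwrite(Path(path), arr)


def write_float_tiff(values: np.ndarray, path: str | Path) -> None:
    """Write a float image/stack (e.g. a distance map, µm) as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))


def read_annotations(path: str | Path) -> list[CellAnnotation]:
    """Read a JSON annotation sidecar listing one or more cells.

    Format::

        {"image": "x.tif",
         "cells": [{"cell_id": "c1",
                    "axis": [[y, x], [y, x]],
                    "outline": [[y, x], ...]}]}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"malformed annotation JSON in {path}: {exc}") from exc
    if not isinstance(doc, dict) or "cells" not in doc:
        raise ValidationError(f"{path}: annotation file must contain a 'cells' list")
    anns = []
    seen: set[str] = set()
    for entry in doc["cells"]:
        cid = str(entry.get("cell_id"))
        if cid in seen:
            raise ValidationError(f"duplicate cell_id {cid!r} in {path}")
        seen.add(cid)
        anns.append(CellAnnotation(cell_id=cid, axis=entry["axis"], outline=entry["outline"]))
    return anns


def write_annotations(anns: list[CellAnnotation], path: str | Path, image: str = "") -> None:
    doc = {
        "image": image,
        "cells": [
            {
                "cell_id": a.cell_id,
                "axis": np.asarray(a.axis).tolist(),
                "outline": np.asarray(a.outline).tolist(),
            }
            for a in anns
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def metrics_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    rows = []
    extra_cols: list[str] = []
    for r in reports:
        for k in r.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    for r in reports:
        r.validate()
        rows.append(
            {
                "cell_id": r.cell_id,
                "mode": r.mode,
                "density_raw": r.density_raw,
                "density_skeleton": r.density_skeleton,
                "fraction_transverse": r.fraction_transverse,
                "fraction_longitudinal": r.fraction_longitudinal,
                "fraction_ambiguous": r.fraction_ambiguous,
                "distance_mean_um": r.distance_mean,
                "distance_median_um": r.distance_median,
                "distance_max_um": r.distance_max,
                "distance_sd_um": r.distance_sd,
                "flags": r.flags,
                **{k: r.extra.get(k, float("nan")) for k in extra_cols},
            }
        )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS + extra_cols)


def write_metrics(reports: list[MetricsReport], path: str | Path) -> None:
    """Write per-cell metrics as a tab-separated table, one row per cell.

    Values are printed with 9 significant digits; re-reading reproduces them
    to better than 1e-6 relative.  Input order is preserved.
    """
    if not reports:
        raise ValidationError("no reports to write")
    frame = metrics_to_frame(reports)
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.9g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", keep_default_na=False, na_values=["nan", "NaN"])
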