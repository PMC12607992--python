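"""Patch-wise order-degree analysis of micrographs.

A micrograph is tiled into overlapping patches; the regression network
predicts an order degree per patch and the structure-tensor oracle adds a
training-free second opinion (raw and calibrated nematic order).  Because
a real fiber mat is heterogeneous, the result is reported as a range
[min, max] of patch predictions rather than a single number, with patches
above the 0.5 order-disorder threshold flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import orientation
from .network import TrainedModel, predict
from .orientation import DegenerateInputError

__all__ = [
    "Micrograph",
    "PatchResult",
    "OrderReport",
    "load_micrograph",
    "preprocess",
    "predict_range",
    "save_report",
    "overlay_image",
]

ORDER_DISORDER_THRESHOLD = 0.5


@dataclass
class Micrograph:
    """Grayscale raster with an optional exclusion mask (True = excluded).

    The mask flags annotation regions — scale bars, text banners — that
    must not contribute patches to the report.
    """

    pixels: np.ndarray
    mask: np.ndarray | None = None
    magnification: str | None = None

    def __post_init__(self) -> None:
        if self.mask is not None and self.mask.shape != self.pixels.shape:
            raise ValueError("mask must have the same shape as pixels")


@dataclass
class PatchResult:
    row: int  # top-left corner, pixels
    col: int
    size: int
    prediction: float  # network order degree
    oracle_S: float | None  # raw nematic order, None if degenerate patch
    oracle_S_calibrated: float | None
    exceeds_threshold: bool


@dataclass
class OrderReport:
    patches: list[PatchResult]
    min: float
    max: float
    mean: float
    std: float
    patch_size: int
    stride: int
    flags: list[str] = field(default_factory=list)
    model_digest: str | None = None

    def summary_range(self) -> tuple[float, float]:
        return self.min, self.max

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "row": p.row,
                    "col": p.col,
                    "size": p.size,
                    "prediction": p.prediction,
                    "oracle_S": p.oracle_S,
                    "oracle_S_calibrated": p.oracle_S_calibrated,
                    "exceeds_threshold": p.exceeds_threshold,
                }
                for p in self.patches
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "summary": {
                    "min": self.min,
                    "max": self.max,
                    "mean": self.mean,
                    "std": self.std,
                    "n_patches": len(self.patches),
                    "order_disorder_threshold": ORDER_DISORDER_THRESHOLD,
                },
                "patch_size": self.patch_size,
                "stride": self.stride,
                "flags": self.flags,
                "model_digest": self.model_digest,
                "patches": self.to_frame().to_dict(orient="records"),
            },
            indent=1,
        )


def load_micrograph(
    path: str | Path,
    mask_rects: list[tuple[int, int, int, int]] | None = None,
    magnification: str | None = None,
) -> Micrograph:
    """Read a PNG/TIFF micrograph (8- or 16-bit, gray or RGB).

    ``mask_rects`` are ``(x, y, w, h)`` rectangles to exclude (e.g. scale
    bars); pixel values are kept in their native integer range here and
    normalized later by :func:`preprocess`.
    """
    raw = iio.imread(Path(path))
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim == 3:  # RGB(A) -> luminance
        raw = raw[..., :3].mean(axis=-1)
    mask = None
    if mask_rects:
        mask = np.zeros(raw.shape, dtype=bool)
        for x, y, w, h in mask_rects:
            mask[y : y + h, x : x + w] = True
    return Micrograph(pixels=raw, mask=mask, magnification=magnification)


def preprocess(micrograph: Micrograph) -> tuple[np.ndarray, np.ndarray]:
    """Normalize intensities to [0, 1] and return (raster, valid mask).

    Robust normalization clips at the 0.5/99.5 percentiles of the unmasked
    pixels; if those coincide (near-constant image) it falls back to
    max-min scaling, and a fully constant image maps to 0.5 everywhere.
    """
    pixels = np.asarray(micrograph.pixels, dtype=np.float64)
    excluded = (
        micrograph.mask
        if micrograph.mask is not None
        else np.zeros(pixels.shape, dtype=bool)
    )
    valid = ~excluded
    if not np.any(valid):
        raise ValueError("micrograph is fully masked")
    values = pixels[valid]
    lo, hi = np.percentile(values, [0.5, 99.5])
    if hi - lo <= 0:
        lo, hi = values.min(), values.max()
    if hi - lo <= 0:
        return np.full(pixels.shape, 0.5), valid
    return np.clip((pixels - lo) / (hi - lo), 0.0, 1.0), valid


def iter_patches(
    shape: tuple[int, int], patch_size: int, stride: int
) -> list[tuple[int, int]]:
    """Top-left corners of a full tiling; the last row/column is shifted
    inward so the border is always covered."""
    h, w = shape
    if h < patch_size or w < patch_size:
        raise ValueError("micrograph smaller than one patch")
    rows = list(range(0, h - patch_size + 1, stride))
    cols = list(range(0, w - patch_size + 1, stride))
    if rows[-1] != h - patch_size:
        rows.append(h - patch_size)
    if cols[-1] != w - patch_size:
        cols.append(w - patch_size)
    return [(r, c) for r in rows for c in cols]


def predict_range(
    micrograph: Micrograph,
    model: TrainedModel,
    patch_size: int = 256,
    stride: int = 128,
    run_oracle: bool = True,
) -> OrderReport:
    """Tile the valid region and report patch predictions and their range.

    Patches overlapping an excluded region are dropped.  With fewer than
    two valid patches the report still comes out, carrying a
    ``single_patch`` warning flag.
    """
    if stride < max(1, patch_size // 2):
        raise ValueError("stride must be at least patch_size / 2")
    raster, valid = preprocess(micrograph)
    results: list[PatchResult] = []
    calibration = orientation.load_default_calibration()
    for r, c in iter_patches(raster.shape, patch_size, stride):
        window_valid = valid[r : r + patch_size, c : c + patch_size]
        if not np.all(window_valid):
            continue
        patch = raster[r : r + patch_size, c : c + patch_size]
        pred = predict(model, patch)
        s_raw = s_cal = None
        if run_oracle:
            try:
                est = orientation.estimate_order(patch, calibration=calibration)
                s_raw, s_cal = est.S, est.S_calibrated
            except DegenerateInputError:
                pass
        results.append(
            PatchResult(
                row=r,
                col=c,
                size=patch_size,
                prediction=pred,
                oracle_S=s_raw,
                oracle_S_calibrated=s_cal,
                exceeds_threshold=pred > ORDER_DISORDER_THRESHOLD,
            )
        )
    if not results:
        raise ValueError("no patch lies fully inside the valid region")
    preds = np.array([p.prediction for p in results])
    flags = ["single_patch"] if len(results) < 2 else []
    return OrderReport(
        patches=results,
        min=float(preds.min()),
        max=float(preds.max()),
        mean=float(preds.mean()),
        std=float(preds.std()),
        patch_size=patch_size,
        stride=stride,
        flags=flags,
        model_digest=model.config_digest,
    )


def save_report(report: OrderReport, base_path: str | Path) -> tuple[Path, Path]:
    """Write the report as JSON plus a flat CSV (one row per patch)."""
    base = Path(base_path)
    json_path = base.with_suffix(".json")
    csv_path = base.with_suffix(".csv")
    json_path.write_text(report.to_json())
    report.to_frame().to_csv(csv_path, index=False)
    return json_path, csv_path


def overlay_image(
    micrograph: Micrograph, report: OrderReport, path: str | Path | None = None
) -> np.ndarray:
    """Render a per-patch prediction heat map over the normalized raster.

    The output is an 8-bit RGB image: the green channel carries the mean
    patch prediction at each pixel, scaled so 0 maps to dark and 1 to
    bright; the blue channel holds the raster.
    """
    raster, _ = preprocess(micrograph)
    heat = np.zeros(raster.shape)
    count = np.zeros(raster.shape)
    for p in report.patches:
        heat[p.row : p.row + p.size, p.col : p.col + p.size] += p.prediction
        count[p.row : p.row + p.size, p.col : p.col + p.size] += 1
    with np.errstate(invalid="ignore"):
        heat = np.where(count > 0, heat / np.maximum(count, 1), 0.0)
    rgb = np.stack(
        [raster * 0.3, heat, raster], axis=-1
    )
    out = np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    if path is not None:
        iio.imwrite(Path(path), out)
    return out
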