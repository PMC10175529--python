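"""Rigid registration and circular ROI handling.

Scans are aligned to a reference by translation only: between table
repositionings the phantom cannot meaningfully rotate at this level of
abstraction, so rotation is fixed at zero.  The estimated sub-pixel
shift is applied to the ROI centers (never by resampling the image, so
interpolation cannot contaminate the texture features), and every ROI
uses one shared circular stencil so all sixteen masks contain the same
number of pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom_synth import (MATRIX_SIZE, PIXEL_SPACING_MM, PhantomSpec,
                            ScanImage)

__all__ = [
    "RigidTransform",
    "ROISet",
    "estimate_rigid",
    "make_roi_masks",
    "extract_roi_values",
    "mean_ct_number",
    "circle_stencil",
]

MAX_SHIFT_PX = 20.0  # sanity bound on plausible repositioning


class DegenerateImageError(ValueError):
    """Raised when an image has no foreground after thresholding."""


@dataclass(frozen=True)
class RigidTransform:
    """Translation (rotation fixed at 0) mapping reference -> image.

    ``dx_px`` moves along columns, ``dy_px`` along rows: content located
    at (r, c) in the reference sits at (r + dy, c + dx) in the image.
    """

    dx_px: float
    dy_px: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dx_px) and np.isfinite(self.dy_px)):
            raise ValueError("transform must be finite")
        if abs(self.dx_px) > MAX_SHIFT_PX or abs(self.dy_px) > MAX_SHIFT_PX:
            raise ValueError(f"implausible shift ({self.dx_px}, {self.dy_px})")


@dataclass(frozen=True)
class ROISet:
    """Sixteen circular ROI masks, one per insert, sharing one stencil."""

    roi_ids: tuple[int, ...]
    centers_px: dict[int, tuple[int, int]]  # roi_id -> (row, col), stencil anchor
    diameter_px: int
    masks: dict[int, np.ndarray]  # roi_id -> boolean 512x512

    def label_map(self) -> np.ndarray:
        """Label image with ROI ids 1–16 (0 = background)."""
        lab = np.zeros((MATRIX_SIZE, MATRIX_SIZE), dtype=np.int16)
        for rid in self.roi_ids:
            lab[self.masks[rid]] = rid
        return lab

    def centers_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"roi_id": rid, "row_px": rc[0], "col_px": rc[1]}
             for rid, rc in sorted(self.centers_px.items())])


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:  # not a peak / flat: no refinement
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_rigid(image: ScanImage, reference: ScanImage, *,
                   threshold_hu: float = -500.0,
                   max_shift_px: float = MAX_SHIFT_PX) -> RigidTransform:
    """Estimate the translation of ``image`` relative to ``reference``.

    Both images are thresholded at ``threshold_hu`` (keeping the phantom
    disk, discarding air), and the translation maximizing the normalized
    cross-correlation of the zero-mean binary foregrounds is located on
    the integer grid by FFT correlation and refined to sub-pixel
    precision by quadratic interpolation of the correlation peak.
    """
    if image.pixels.shape != reference.pixels.shape:
        raise ValueError("image and reference must share shape")
    a = (reference.pixels > threshold_hu).astype(float)
    b = (image.pixels > threshold_hu).astype(float)
    if a.sum() == 0 or b.sum() == 0:
        raise DegenerateImageError("no foreground above threshold")
    a -= a.mean()
    b -= b.mean()
    # corr[s] = sum_r a[r] * b[r + s]  (circular; content is far from edges)
    corr = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    corr = np.fft.fftshift(corr)
    n = corr.shape[0]
    c0 = n // 2
    w = int(np.ceil(max_shift_px))
    win = corr[c0 - w:c0 + w + 1, c0 - w:c0 + w + 1]
    pr, pc = np.unravel_index(np.argmax(win), win.shape)
    dy = pr - w
    dx = pc - w
    # quadratic sub-pixel refinement along each axis
    gr, gc = c0 + dy, c0 + dx
    sub_dy = _parabolic_offset(corr[gr - 1, gc], corr[gr, gc], corr[gr + 1, gc])
    sub_dx = _parabolic_offset(corr[gr, gc - 1], corr[gr, gc], corr[gr, gc + 1])
    return RigidTransform(dx_px=dx + sub_dx, dy_px=dy + sub_dy)


def circle_stencil(diameter_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/col offsets of lattice points within ``diameter_px/2`` of the origin.

    Pixel-inclusion rule: a pixel belongs to the ROI iff its center lies
    at distance <= radius from the ROI center (26 px diameter -> 529 px).
    """
    r = diameter_px / 2.0
    span = int(np.floor(r))
    off = np.arange(-span, span + 1)
    dr, dc = np.meshgrid(off, off, indexing="ij")
    keep = dr ** 2 + dc ** 2 <= r ** 2
    return dr[keep], dc[keep]


def make_roi_masks(spec: PhantomSpec, transform: RigidTransform,
                   diameter_px: int = 26, *,
                   shape: tuple[int, int] = (MATRIX_SIZE, MATRIX_SIZE),
                   pixel_spacing_mm: float = PIXEL_SPACING_MM) -> ROISet:
    """Place one circular ROI at the (transformed) center of each insert.

    Insert centers are converted mm -> px, shifted by the transform, and
    rounded to the nearest pixel; the common stencil is then stamped at
    the rounded center so every ROI has an identical pixel count.
    """
    dr, dc = circle_stencil(diameter_px)
    half = (shape[0] - 1) / 2.0
    roi_ids = []
    centers: dict[int, tuple[int, int]] = {}
    masks: dict[int, np.ndarray] = {}
    for ins in spec.inserts:
        col = half + ins.center_xy[0] / pixel_spacing_mm + transform.dx_px
        row = half + ins.center_xy[1] / pixel_spacing_mm + transform.dy_px
        r0, c0 = int(round(row)), int(round(col))
        rr, cc = r0 + dr, c0 + dc
        if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
            raise ValueError(f"ROI {ins.insert_id} extends beyond image bounds")
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        roi_ids.append(ins.insert_id)
        centers[ins.insert_id] = (r0, c0)
        masks[ins.insert_id] = m
    return ROISet(roi_ids=tuple(roi_ids), centers_px=centers,
                  diameter_px=diameter_px, masks=masks)


def extract_roi_values(image: ScanImage, mask: np.ndarray) -> np.ndarray:
    """HU values of the masked pixels in row-major order."""
    if mask.shape != image.pixels.shape:
        raise ValueError("mask and image shapes differ")
    return image.pixels[mask].copy()


def mean_ct_number(image: ScanImage, mask: np.ndarray) -> float:
    """Mean HU inside the ROI (the per-insert CT number)."""
    return float(extract_roi_values(image, mask).mean())
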