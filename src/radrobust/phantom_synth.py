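"""Synthetic multi-platform dual-energy CT phantom images.

The simulated object is a 330 mm water-equivalent disk holding sixteen
28 mm cylindrical inserts: five iodine solutions (2.0–15.0 mg/mL) and
eleven tissue-mimicking density rods (0.44–1.69 g/cm³), imaged as a
single 512×512 axial slice over a 500×500 mm field of view.

Each "imaging platform" is a phenomenological surrogate for one
dual-energy CT acquisition/reconstruction chain.  Instead of modelling
X-ray physics, a platform perturbs the reference CT numbers with a
global HU bias and per-insert HU deviations (different for virtual
unenhanced, VUE, and 70 keV virtual monoenergetic, VMI70keV, images),
adds Gaussian noise, and applies a Gaussian smoothing kernel standing in
for the reconstruction kernel.  Repeated scans reposition the phantom by
a small random rigid translation, as happens when the phantom is taken
off and put back on the table.

Everything is a pure function of explicit seeds, so any scan can be
regenerated independently of the others.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "IMAGE_TYPES",
    "VUE",
    "VMI70KEV",
    "MATRIX_SIZE",
    "FOV_MM",
    "PIXEL_SPACING_MM",
    "SLICE_THICKNESS_MM",
    "AIR_HU",
    "InsertSpec",
    "PhantomSpec",
    "PlatformModel",
    "ScanImage",
    "default_phantom_spec",
    "default_platform_models",
    "simulate_scan",
    "simulate_study",
    "scan_seed",
    "load_scan",
]

VUE = "VUE"
VMI70KEV = "VMI70keV"
IMAGE_TYPES = (VUE, VMI70KEV)

MATRIX_SIZE = 512
FOV_MM = 500.0
PIXEL_SPACING_MM = FOV_MM / MATRIX_SIZE  # 0.9765625 mm
SLICE_THICKNESS_MM = 5.0
AIR_HU = -1000.0

DISK_DIAMETER_MM = 330.0
INSERT_DIAMETER_MM = 28.0

# Gaussian FWHM -> sigma
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class InsertSpec:
    """One phantom insert: an iodine solution or a density rod."""

    insert_id: int
    label: str
    kind: str  # "iodine" | "density_rod"
    nominal_value: float  # mg/mL for iodine, g/cm^3 for rods
    center_xy: tuple[float, float]  # mm relative to disk center
    reference_hu: Mapping[str, float]  # image_type -> HU on the reference platform


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and reference CT numbers of the phantom."""

    disk_diameter_mm: float = DISK_DIAMETER_MM
    insert_diameter_mm: float = INSERT_DIAMETER_MM
    inserts: tuple[InsertSpec, ...] = ()
    background_hu: float = 0.0

    def validate(self) -> None:
        if len(self.inserts) != 16:
            raise ValueError(f"phantom must hold 16 inserts, got {len(self.inserts)}")
        r_max = self.disk_diameter_mm / 2.0 - self.insert_diameter_mm / 2.0
        centers = np.array([ins.center_xy for ins in self.inserts], float)
        radii = np.hypot(centers[:, 0], centers[:, 1])
        if np.any(radii > r_max + 1e-9):
            raise ValueError("insert centers must lie fully inside the disk")
        d = np.hypot(centers[:, None, 0] - centers[None, :, 0],
                     centers[:, None, 1] - centers[None, :, 1])
        np.fill_diagonal(d, np.inf)
        if d.min() <= self.insert_diameter_mm:
            raise ValueError("inserts overlap given 28 mm diameter")
        for ins in self.inserts:
            if ins.kind == "iodine" and not (2.0 <= ins.nominal_value <= 15.0):
                raise ValueError(f"iodine concentration out of range: {ins}")
            if ins.kind == "density_rod" and not (0.44 <= ins.nominal_value <= 1.69):
                raise ValueError(f"rod density out of range: {ins}")


@dataclass(frozen=True)
class PlatformModel:
    """Phenomenological surrogate for one DECT imaging platform.

    ``hu_bias`` shifts every in-disk pixel of one image type; the
    per-insert ``hu_insert_deviation`` models material-decomposition and
    calibration differences; ``noise_sd`` and ``kernel_fwhm_px`` stand in
    for dose/reconstruction differences.  Platform 1 is by convention the
    reference: zero bias and zero deviations.
    """

    platform_id: int
    scanner_type: str  # "dsDECT" | "rsDECT" | "dlDECT"
    hu_bias: Mapping[str, float]
    hu_insert_deviation: Mapping[tuple[str, int], float]
    noise_sd: Mapping[str, float]
    kernel_fwhm_px: float
    air_hu: float = AIR_HU

    def insert_hu(self, spec: PhantomSpec, insert: InsertSpec, image_type: str) -> float:
        """Analytic (noise-free) HU of an insert on this platform."""
        return (insert.reference_hu[image_type]
                + self.hu_bias[image_type]
                + self.hu_insert_deviation[(image_type, insert.insert_id)])


@dataclass(frozen=True)
class ScanImage:
    """One reconstructed 512×512 slice in Hounsfield units."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    platform_id: int
    image_type: str
    repeat_idx: int
    applied_shift_px: tuple[float, float]  # (dx=cols, dy=rows) ground truth
    seed_used: int

    def __post_init__(self) -> None:
        if self.pixels.shape != (MATRIX_SIZE, MATRIX_SIZE):
            raise ValueError(f"scan must be {MATRIX_SIZE}x{MATRIX_SIZE}")


def _default_inserts() -> tuple[InsertSpec, ...]:
    # Iodine: on VMI70keV HU grows ~25 HU per mg/mL; on VUE the iodine is
    # (almost) removed, leaving a small residual.
    iodine = [("iodine 2.0 mg/mL", 2.0), ("iodine 5.0 mg/mL", 5.0),
              ("iodine 7.5 mg/mL", 7.5), ("iodine 10.0 mg/mL", 10.0),
              ("iodine 15.0 mg/mL", 15.0)]
    # (label, density g/cm^3, HU) — identical on both image types.
    rods = [("lung LN-450", 0.44, -540.0),
            ("adipose", 0.94, -90.0),
            ("breast", 0.98, -40.0),
            ("solid water", 1.015, 5.0),
            ("brain", 1.05, 30.0),
            ("liver", 1.09, 90.0),
            ("inner bone", 1.14, 210.0),
            ("bone mineral B200", 1.15, 230.0),
            ("bone CB2-30%", 1.33, 450.0),
            ("bone CB2-50%", 1.56, 780.0),
            ("dense bone", 1.69, 1000.0)]
    entries: list[tuple[str, str, float, dict[str, float]]] = []
    for label, conc in iodine:
        entries.append((label, "iodine", conc,
                        {VUE: 0.4 * conc, VMI70KEV: 25.0 * conc}))
    for label, dens, hu in rods:
        entries.append((label, "density_rod", dens, {VUE: hu, VMI70KEV: hu}))

    # Interleave low/high attenuation so dense inserts are never adjacent
    # (mimics placement chosen to limit beam-hardening artifacts).
    entries.sort(key=lambda e: e[3][VMI70KEV])
    order: list[tuple[str, str, float, dict[str, float]]] = []
    lo, hi = 0, len(entries) - 1
    while lo <= hi:
        order.append(entries[lo])
        if hi > lo:
            order.append(entries[hi])
        lo += 1
        hi -= 1

    # 12 holes on an outer ring (r=110 mm), 4 on an inner ring (r=55 mm).
    positions: list[tuple[float, float]] = []
    for k in range(12):
        a = np.deg2rad(30.0 * k)
        positions.append((110.0 * np.cos(a), 110.0 * np.sin(a)))
    for k in range(4):
        a = np.deg2rad(45.0 + 90.0 * k)
        positions.append((55.0 * np.cos(a), 55.0 * np.sin(a)))

    inserts = tuple(
        InsertSpec(insert_id=i + 1, label=lab, kind=kind, nominal_value=val,
                   center_xy=positions[i], reference_hu=hu)
        for i, (lab, kind, val, hu) in enumerate(order)
    )
    return inserts


def default_phantom_spec() -> PhantomSpec:
    """The default 16-insert phantom layout.

    The physical phantom does not prescribe which hole holds which
    insert; the layout here (outer ring of 12, inner ring of 4, dense and
    light inserts interleaved) is this package's documented convention.
    Reference HU span roughly −540 (lung rod) to +1000 (dense bone).
    """
    spec = PhantomSpec(inserts=_default_inserts())
    spec.validate()
    return spec


def default_platform_models(
    n_platforms: int,
    seed: int,
    spread_hu: float,
    *,
    vue_spread_factor: float = 2.0,
    bias_sd_hu: float = 5.0,
    noise_sd_hu: float = 10.0,
    kernel_fwhm_px: float = 2.0,
    kernel_jitter: float = 0.25,
    insert_spread_scale: Mapping[int, float] | None = None,
    n_inserts: int = 16,
) -> list[PlatformModel]:
    """Seeded surrogate platform models.

    Platform 1 is the zero-bias/zero-deviation reference.  Per-insert HU
    deviations for the other platforms are drawn N(0, spread) with
    spread = ``spread_hu`` for VMI70keV and ``spread_hu * vue_spread_factor``
    for VUE — encoding that virtual monoenergetic images show lower
    CT-number variability across platforms than virtual unenhanced
    images.  ``insert_spread_scale`` multiplies the deviation SD of
    selected inserts, which makes the platform offsets heterogeneous
    across inserts.  Reconstruction-kernel differences are emulated by a
    per-platform smoothing FWHM jittered around ``kernel_fwhm_px``.
    """
    if n_platforms < 2:
        raise ValueError("need at least 2 platforms")
    if spread_hu < 0:
        raise ValueError("spread_hu must be >= 0")
    rng = np.random.default_rng(seed)
    scale = dict(insert_spread_scale or {})
    models: list[PlatformModel] = []
    for pid in range(1, n_platforms + 1):
        if pid <= 6:
            stype = "dsDECT"
        elif pid <= 9:
            stype = "rsDECT"
        else:
            stype = "dlDECT"
        if pid == 1:
            bias = {t: 0.0 for t in IMAGE_TYPES}
            dev = {(t, i): 0.0 for t in IMAGE_TYPES for i in range(1, n_inserts + 1)}
            fwhm = kernel_fwhm_px
        else:
            bias = {}
            dev = {}
            for t in IMAGE_TYPES:
                s = spread_hu * (vue_spread_factor if t == VUE else 1.0)
                bias[t] = float(rng.normal(0.0, bias_sd_hu))
                for i in range(1, n_inserts + 1):
                    dev[(t, i)] = float(rng.normal(0.0, s * scale.get(i, 1.0)))
            fwhm = float(kernel_fwhm_px *
                         rng.uniform(1.0 - kernel_jitter, 1.0 + kernel_jitter))
        models.append(PlatformModel(
            platform_id=pid, scanner_type=stype, hu_bias=bias,
            hu_insert_deviation=dev,
            noise_sd={t: noise_sd_hu for t in IMAGE_TYPES},
            kernel_fwhm_px=fwhm))
    return models


def _pixel_coords_mm() -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (x along columns, y along rows) in mm."""
    c = (np.arange(MATRIX_SIZE) - (MATRIX_SIZE - 1) / 2.0) * PIXEL_SPACING_MM
    return np.meshgrid(c, c, indexing="xy")


def rasterize(spec: PhantomSpec, platform: PlatformModel, image_type: str,
              shift_px: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Noise-free HU image of the (possibly shifted) phantom.

    ``shift_px`` = (dx, dy) moves the whole phantom by dx pixels along
    columns and dy along rows.  A pixel takes the HU of the region its
    center falls in: insert > disk background > air.
    """
    if image_type not in IMAGE_TYPES:
        raise ValueError(f"unknown image type {image_type!r}; expected one of {IMAGE_TYPES}")
    dx_mm = shift_px[0] * PIXEL_SPACING_MM
    dy_mm = shift_px[1] * PIXEL_SPACING_MM
    X, Y = _pixel_coords_mm()
    img = np.full((MATRIX_SIZE, MATRIX_SIZE), platform.air_hu, dtype=float)
    r_disk = spec.disk_diameter_mm / 2.0
    in_disk = (X - dx_mm) ** 2 + (Y - dy_mm) ** 2 <= r_disk ** 2
    img[in_disk] = spec.background_hu + platform.hu_bias[image_type]
    r_ins = spec.insert_diameter_mm / 2.0
    for ins in spec.inserts:
        cx = ins.center_xy[0] + dx_mm
        cy = ins.center_xy[1] + dy_mm
        m = (X - cx) ** 2 + (Y - cy) ** 2 <= r_ins ** 2
        img[m] = platform.insert_hu(spec, ins, image_type)
    return img


def simulate_scan(spec: PhantomSpec, platform: PlatformModel, image_type: str,
                  repeat_idx: int, seed: int, *,
                  max_shift_px: float = 3.0) -> ScanImage:
    """Simulate one reconstructed slice.

    Repeat 1 is acquired with the phantom at its nominal position; later
    repeats reposition it by a uniform ±``max_shift_px`` translation per
    axis (recorded in ``applied_shift_px``).  I.i.d. Gaussian noise is
    added before the Gaussian smoothing so the surviving noise is
    spatially correlated, as reconstruction-kernel noise is.
    """
    if repeat_idx < 1:
        raise ValueError("repeat_idx must be >= 1")
    rng = np.random.default_rng(seed)
    if repeat_idx > 1:
        dx, dy = rng.uniform(-max_shift_px, max_shift_px, size=2)
    else:
        dx = dy = 0.0
    img = rasterize(spec, platform, image_type, (dx, dy))
    sd = platform.noise_sd[image_type]
    if sd > 0:
        img = img + rng.normal(0.0, sd, size=img.shape)
    if platform.kernel_fwhm_px > 0:
        img = ndimage.gaussian_filter(img, platform.kernel_fwhm_px * _FWHM_TO_SIGMA,
                                      mode="nearest")
    return ScanImage(pixels=img, pixel_spacing_mm=PIXEL_SPACING_MM,
                     platform_id=platform.platform_id, image_type=image_type,
                     repeat_idx=repeat_idx, applied_shift_px=(float(dx), float(dy)),
                     seed_used=int(seed))


def scan_seed(master_seed: int, platform_id: int, image_type: str,
              repeat_idx: int) -> int:
    """Deterministic per-scan seed derived from the master seed.

    Uses ``numpy.random.SeedSequence`` so any single scan can be
    regenerated without simulating the rest of the study.
    """
    ss = np.random.SeedSequence(
        [int(master_seed), int(platform_id), IMAGE_TYPES.index(image_type),
         int(repeat_idx)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


MANIFEST_COLUMNS = ["file_path", "platform_id", "image_type", "repeat_idx",
                    "seed", "dx_px", "dy_px"]


def simulate_study(spec: PhantomSpec, platforms: Sequence[PlatformModel],
                   image_types: Sequence[str], n_repeats: int, seed: int,
                   out_dir: str | os.PathLike | None = None,
                   ) -> tuple[pd.DataFrame, list[ScanImage]]:
    """Full factorial study: platforms × image types × repeats.

    Returns the manifest (one row per scan) and the scans themselves.
    When ``out_dir`` is given, each scan is written as a NIfTI file and
    the manifest as ``manifest.csv`` alongside them.
    """
    if n_repeats < 2:
        raise ValueError("test–retest analysis needs n_repeats >= 2")
    rows = []
    scans: list[ScanImage] = []
    for platform in platforms:
        for itype in image_types:
            for rep in range(1, n_repeats + 1):
                s = scan_seed(seed, platform.platform_id, itype, rep)
                scan = simulate_scan(spec, platform, itype, rep, s)
                scans.append(scan)
                fname = f"platform{platform.platform_id:02d}_{itype}_rep{rep}.nii.gz"
                rows.append({"file_path": fname,
                             "platform_id": platform.platform_id,
                             "image_type": itype, "repeat_idx": rep, "seed": s,
                             "dx_px": scan.applied_shift_px[0],
                             "dy_px": scan.applied_shift_px[1]})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        for scan, row in zip(scans, rows):
            _write_nifti(scan, os.path.join(out_dir, row["file_path"]))
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest, scans


def _write_nifti(scan: ScanImage, path: str) -> None:
    import nibabel as nib

    affine = np.diag([scan.pixel_spacing_mm, scan.pixel_spacing_mm,
                      SLICE_THICKNESS_MM, 1.0])
    data = scan.pixels.astype(np.float32)[:, :, None]
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((scan.pixel_spacing_mm, scan.pixel_spacing_mm,
                          SLICE_THICKNESS_MM))
    nib.save(img, path)


def load_scan(path: str | os.PathLike, platform_id: int, image_type: str,
              repeat_idx: int, seed: int = -1,
              applied_shift_px: tuple[float, float] = (np.nan, np.nan)) -> ScanImage:
    """Read a NIfTI slice back into a :class:`ScanImage`."""
    import nibabel as nib

    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[:, :, 0]
    return ScanImage(pixels=data, pixel_spacing_mm=float(img.header.get_zooms()[0]),
                     platform_id=platform_id, image_type=image_type,
                     repeat_idx=repeat_idx,
                     applied_shift_px=tuple(float(v) for v in applied_shift_px),
                     seed_used=int(seed))
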