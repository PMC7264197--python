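"""Detector geometry, image containers and image-plane operations.

The mapping between detector pixels and reciprocal space uses the exact
Bragg relation per axis::

    d = λ / (2 sin θ),   θ = ½·atan(x / SDD)

where ``x`` is the in-plane offset from the beam center along the axis
(mm) and ``SDD`` the sample-detector distance (mm).  At small-angle
geometries this agrees with the flat-detector approximation q ≈ x/(λ·SDD)
to < 0.01%, but the exact form round-trips cleanly.

Coordinate convention: image row 0 is the top of the raster; the meridian
(fiber axis) is the vertical line through the beam center, the equator the
horizontal one.  Axial reciprocal coordinates (z) are positive above the
center and quoted in Å⁻¹; radial coordinates (r) are positive to the right
of the meridian and quoted in nm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from . import units


class GeometryError(ValueError):
    """Invalid detector geometry or out-of-bounds pixel."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry for a fiber-diffraction experiment.

    Parameters
    ----------
    sample_detector_distance_mm:
        Sample-to-detector distance (mm).
    pixel_size_um:
        Square pixel edge (µm); 172 µm for a Pilatus-style detector.
    beam_center:
        (row, col) of the beam center in pixel units; fractional allowed.
    photon_energy_kev:
        Beam energy in keV (12 keV default).
    image_shape:
        (rows, cols) of the detector raster.
    """

    sample_detector_distance_mm: float
    pixel_size_um: float = 172.0
    beam_center: tuple[float, float] = (0.0, 0.0)
    photon_energy_kev: float = 12.0
    image_shape: tuple[int, int] = (981, 1043)

    def __post_init__(self) -> None:
        if self.sample_detector_distance_mm <= 0:
            raise GeometryError("sample-detector distance must be positive")
        if self.pixel_size_um <= 0:
            raise GeometryError("pixel size must be positive")
        if self.photon_energy_kev <= 0:
            raise GeometryError("photon energy must be positive")
        nrow, ncol = self.image_shape
        r0, c0 = self.beam_center
        if not (0 <= r0 <= nrow - 1 and 0 <= c0 <= ncol - 1):
            raise GeometryError("beam center outside image bounds")

    @property
    def wavelength_angstrom(self) -> float:
        """λ (Å), computed from the photon energy — never stored."""
        return units.wavelength_angstrom(self.photon_energy_kev)

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um * 1e-3

    # ---- per-axis exact Bragg mapping -------------------------------------

    def offset_mm_to_q_inv_a(self, offset_mm: np.ndarray | float) -> np.ndarray | float:
        """Signed in-plane offset (mm) → signed reciprocal coordinate (Å⁻¹)."""
        offset_mm = np.asarray(offset_mm, dtype=float)
        theta = 0.5 * np.arctan(offset_mm / self.sample_detector_distance_mm)
        q = 2.0 * np.sin(theta) / self.wavelength_angstrom
        return q if q.ndim else float(q)

    def q_inv_a_to_offset_mm(self, q_inv_a: np.ndarray | float) -> np.ndarray | float:
        """Inverse of :meth:`offset_mm_to_q_inv_a`."""
        q = np.asarray(q_inv_a, dtype=float)
        s = q * self.wavelength_angstrom / 2.0
        if np.any(np.abs(s) >= 1.0):
            raise GeometryError("reciprocal coordinate beyond the detector sphere")
        offset = self.sample_detector_distance_mm * np.tan(2.0 * np.arcsin(s))
        return offset if offset.ndim else float(offset)

    def reciprocal_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Signed (r, z) maps of the detector face.

        Returns ``(r_nm, z_a)``: radial coordinate in nm⁻¹ (positive right
        of the meridian) and axial coordinate in Å⁻¹ (positive above the
        equator), each shaped like the image.
        """
        nrow, ncol = self.image_shape
        r0, c0 = self.beam_center
        # rows increase downward, so axial offset is (r0 - row)
        z_off = (r0 - np.arange(nrow)) * self.pixel_size_mm
        r_off = (np.arange(ncol) - c0) * self.pixel_size_mm
        z_a = np.asarray(self.offset_mm_to_q_inv_a(z_off))
        r_a = np.asarray(self.offset_mm_to_q_inv_a(r_off))
        r_nm = units.inv_angstrom_to_inv_nm(r_a)
        return (
            np.broadcast_to(r_nm[None, :], self.image_shape),
            np.broadcast_to(z_a[:, None], self.image_shape),
        )


@dataclass(frozen=True)
class ReciprocalCoord:
    """A point in reciprocal space: radial r (nm⁻¹) and axial z (Å⁻¹), signed."""

    r_inv_nm: float
    z_inv_a: float

    @property
    def axial_spacing_angstrom(self) -> float:
        return units.spacing_angstrom(abs(self.z_inv_a))

    @property
    def radial_spacing_nm(self) -> float:
        return units.spacing_nm(abs(self.r_inv_nm))


def pixel_to_reciprocal(px: tuple[float, float], geom: DetectorGeometry) -> ReciprocalCoord:
    """Map a (row, col) pixel to its signed reciprocal-space coordinates."""
    row, col = px
    nrow, ncol = geom.image_shape
    if not (-0.5 <= row <= nrow - 0.5 and -0.5 <= col <= ncol - 0.5):
        raise GeometryError(f"pixel {px} outside image bounds {geom.image_shape}")
    r0, c0 = geom.beam_center
    z = geom.offset_mm_to_q_inv_a((r0 - row) * geom.pixel_size_mm)
    r = geom.offset_mm_to_q_inv_a((col - c0) * geom.pixel_size_mm)
    return ReciprocalCoord(units.inv_angstrom_to_inv_nm(r), z)


def reciprocal_to_pixel(coord: ReciprocalCoord, geom: DetectorGeometry) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_reciprocal` (fractional pixel)."""
    r0, c0 = geom.beam_center
    z_off = geom.q_inv_a_to_offset_mm(coord.z_inv_a)
    r_off = geom.q_inv_a_to_offset_mm(units.inv_nm_to_inv_angstrom(coord.r_inv_nm))
    return (r0 - z_off / geom.pixel_size_mm, c0 + r_off / geom.pixel_size_mm)


@dataclass
class DetectorImage:
    """Counts on a detector raster plus geometry and provenance metadata.

    ``mask`` marks bad/missing pixels (detector gaps) as True; masked
    pixels are excluded from folds and projections.  Counts may be
    negative after background subtraction — they are kept signed and the
    fraction of negative pixels is flagged in ``meta``.
    """

    counts: np.ndarray
    geometry: DetectorGeometry
    meta: dict = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != tuple(self.geometry.image_shape):
            raise GeometryError(
                f"counts shape {self.counts.shape} != geometry {self.geometry.image_shape}"
            )
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise GeometryError("mask shape mismatch")

    @property
    def valid(self) -> np.ndarray:
        """Boolean plane of usable pixels."""
        if self.mask is None:
            return np.ones_like(self.counts, dtype=bool)
        return ~self.mask

    def copy_with(self, counts: np.ndarray, **meta) -> "DetectorImage":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return DetectorImage(counts=counts, geometry=self.geometry, meta=new_meta,
                             mask=None if self.mask is None else self.mask.copy())


def average_frames(stack: Sequence[DetectorImage]) -> DetectorImage:
    """Pixelwise mean of a stack of frames sharing one geometry."""
    if len(stack) == 0:
        raise ValueError("cannot average an empty frame stack")
    first = stack[0]
    for img in stack[1:]:
        if img.counts.shape != first.counts.shape:
            raise GeometryError("mismatched frame shapes")
        if img.geometry != first.geometry:
            raise GeometryError("mismatched frame geometries")
    if len(stack) == 1:
        return first
    mean = np.mean([img.counts for img in stack], axis=0)
    return first.copy_with(mean, n_frames_averaged=len(stack))


def _mirror_indices(n: int, center: float) -> tuple[np.ndarray, np.ndarray]:
    """Mirror index i ↦ 2·center − i; returns (mirror, valid) arrays.

    Exact when 2·center is integral (integer or half-integer center).
    """
    two_c = 2.0 * center
    if abs(two_c - round(two_c)) > 1e-9:
        raise GeometryError(
            "quadrant fold requires an integer- or half-integer-aligned beam center"
        )
    mirror = int(round(two_c)) - np.arange(n)
    valid = (mirror >= 0) & (mirror < n)
    return np.clip(mirror, 0, n - 1), valid


def quadrant_fold(img: DetectorImage) -> DetectorImage:
    """Average each pixel with its mirror images about the beam center.

    Every pixel is replaced by the mean of up to four symmetry mates
    (itself, row-mirror, column-mirror, both); mates that fall outside the
    detector or on masked pixels are excluded from the mean.  The
    operation is idempotent and, for a fully unmasked image whose mirrors
    all land on the detector, conserves the mean intensity exactly.
    """
    r0, c0 = img.geometry.beam_center
    nrow, ncol = img.counts.shape
    mrow, vrow = _mirror_indices(nrow, r0)
    mcol, vcol = _mirror_indices(ncol, c0)

    acc = np.zeros_like(img.counts)
    wgt = np.zeros_like(img.counts)
    valid = img.valid.astype(float)
    data = np.where(img.valid, img.counts, 0.0)

    for flip_r in (False, True):
        for flip_c in (False, True):
            rows = mrow if flip_r else np.arange(nrow)
            cols = mcol if flip_c else np.arange(ncol)
            ok_r = vrow if flip_r else np.ones(nrow, bool)
            ok_c = vcol if flip_c else np.ones(ncol, bool)
            sub = data[np.ix_(rows, cols)]
            w = valid[np.ix_(rows, cols)] * np.outer(ok_r, ok_c)
            acc += sub * w
            wgt += w

    out = np.divide(acc, wgt, out=np.zeros_like(acc), where=wgt > 0)
    return img.copy_with(out, quadrant_folded=True)


def subtract_background(
    img: DetectorImage,
    bg: DetectorImage | float | None = None,
) -> tuple[DetectorImage, float]:
    """Subtract a measured background and sum the residual diffuse scatter.

    ``bg`` may be a matched background exposure (beam through the empty
    cell), a constant pedestal, or None.  The returned ``diffuse_sum`` is
    the summed diffuse (azimuthally smooth) intensity of the corrected
    image, estimated from the azimuthal median radial profile; it serves
    as the normalization standard for reflection intensities across
    exposures.  Negative residual pixels are kept signed and their
    fraction recorded in ``meta['negative_fraction']``.
    """
    if bg is None:
        bg_counts = 0.0
    elif isinstance(bg, DetectorImage):
        if bg.counts.shape != img.counts.shape:
            raise GeometryError("background shape mismatch")
        bg_counts = bg.counts
    else:
        bg_counts = float(bg)

    corrected = img.counts - bg_counts
    diffuse = _azimuthal_median_model(corrected, img.geometry, img.valid)
    diffuse_sum = float(np.sum(diffuse[img.valid]))
    neg_frac = float(np.mean(corrected[img.valid] < 0)) if img.valid.any() else 0.0
    out = img.copy_with(corrected, background_subtracted=True,
                        negative_fraction=neg_frac, diffuse_sum=diffuse_sum)
    return out, diffuse_sum


def _azimuthal_median_model(
    counts: np.ndarray, geom: DetectorGeometry, valid: np.ndarray
) -> np.ndarray:
    """Isotropic diffuse model: median intensity per integer-radius annulus.

    The median is robust to the sparse, sharp Bragg features riding on the
    smooth diffuse scatter, so the annular medians track the diffuse
    component alone.
    """
    nrow, ncol = counts.shape
    r0, c0 = geom.beam_center
    yy, xx = np.indices((nrow, ncol))
    rad = np.hypot(yy - r0, xx - c0)
    ring = rad.astype(int)
    nring = int(ring.max()) + 1
    med = np.zeros(nring)
    flat_ring = ring[valid]
    flat_val = counts[valid]
    order = np.argsort(flat_ring, kind="stable")
    flat_ring = flat_ring[order]
    flat_val = flat_val[order]
    bounds = np.searchsorted(flat_ring, np.arange(nring + 1))
    for k in range(nring):
        lo, hi = bounds[k], bounds[k + 1]
        med[k] = np.median(flat_val[lo:hi]) if hi > lo else 0.0
    return med[ring]


# ---- I/O -------------------------------------------------------------------


def read_tiff(path: str | Path, geometry: DetectorGeometry, **meta) -> DetectorImage:
    """Load a 32-bit float TIFF as a detector frame."""
    counts = tifffile.imread(str(path)).astype(float)
    return DetectorImage(counts=counts, geometry=geometry, meta={"path": str(path), **meta})


def write_tiff(path: str | Path, img: DetectorImage) -> None:
    """Write counts as 32-bit float TIFF."""
    tifffile.imwrite(str(path), img.counts.astype(np.float32))


def geometry_from_config(path: str | Path) -> DetectorGeometry:
    """Read a geometry from a YAML config.

    Keys: ``sdd_mm``, ``pixel_um``, ``energy_kev``, ``center_row``,
    ``center_col``, and optional ``shape`` ([rows, cols]).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return geometry_from_dict(cfg)


def geometry_from_dict(cfg: dict) -> DetectorGeometry:
    shape = tuple(cfg.get("shape", (981, 1043)))
    return DetectorGeometry(
        sample_detector_distance_mm=float(cfg["sdd_mm"]),
        pixel_size_um=float(cfg.get("pixel_um", 172.0)),
        beam_center=(float(cfg["center_row"]), float(cfg["center_col"])),
        photon_energy_kev=float(cfg.get("energy_kev", 12.0)),
        image_shape=shape,  # type: ignore[arg-type]
    )


def geometry_to_dict(geom: DetectorGeometry) -> dict:
    return {
        "sdd_mm": geom.sample_detector_distance_mm,
        "pixel_um": geom.pixel_size_um,
        "energy_kev": geom.photon_energy_kev,
        "center_row": geom.beam_center[0],
        "center_col": geom.beam_center[1],
        "shape": list(geom.image_shape),
    }
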