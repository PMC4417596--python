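"""Quantitative CT morphometry: BMD calibration, BV/TV, MIL/TbN, FD, areas.

Attenuation volumes are converted to calcium-hydroxyapatite-equivalent
densities (mg/cm^3) via a linear calibration estimated from phantom rods of
known density.  Trabecular structure is then quantified inside a centred
region of interest: bone volume fraction after a global density threshold,
trabecular number via the mean intercept length (MIL) of the bone phase,
and a box-counting fractal dimension of the binarized transverse slices.
Transverse cross-sectional areas are measured from the specimen mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

DEFAULT_THRESHOLD = 200.0   # mg/cm^3 hydroxyapatite; inclusive (>= is bone)
DEFAULT_BOX_SIZES = (2, 4, 8, 16, 32, 64)


@dataclass
class CTVolume:
    """A 3D attenuation (HU) or density volume with voxel-size metadata."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (0.23, 0.23, 0.6)   # mm, (x, y, z)
    mask: np.ndarray | None = None    # optional specimen mask, same shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3-dimensional")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match volume shape")


@dataclass
class CalibrationModel:
    """Affine HU -> density (mg/cm^3) mapping fitted from phantom rods."""

    slope: float        # mg/cm^3 per HU
    intercept: float    # mg/cm^3
    r_squared: float
    pairs: list[tuple[float, float]]   # (mean HU, nominal density)


@dataclass(frozen=True)
class RoiSpec:
    """Centred in-plane analysis window over the most central slices."""

    extent_mm: tuple[float, float] = (12.0, 12.0)
    n_slices: int = 20

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if any(e <= 0 for e in self.extent_mm):
            raise ValueError("ROI extent must be positive")


@dataclass
class MilResult:
    """Mean-intercept-length morphometry with audit counts."""

    mil_mm: dict[int, float]           # per direction (axis index)
    bone_length_mm: dict[int, float]   # total bone phase length along lines
    n_intercepts: dict[int, int]       # number of bone intercepts
    tb_th_mm: float                    # direction-averaged MIL (Tb.Th*)
    tbn: float                         # mm^-1


@dataclass
class MorphometryResult:
    """Per-specimen morphometric summary."""

    bmd: float        # mg/cm^3
    bv_tv: float      # %
    tbn: float        # mm^-1
    fd: float
    mean_area: float  # cm^2
    min_area: float   # cm^2


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------


def calibrate(phantom_pairs) -> CalibrationModel:
    """Least-squares line of nominal density on measured HU.

    ``phantom_pairs`` is a sequence of (mean HU, nominal density mg/cm^3).
    """
    pairs = [(float(h), float(d)) for h, d in phantom_pairs]
    if len(pairs) < 2:
        raise ValueError("calibration needs at least two phantom rods")
    hu = np.array([p[0] for p in pairs])
    rho = np.array([p[1] for p in pairs])
    if np.ptp(hu) == 0:
        raise ValueError("phantom rods have identical HU; calibration is singular")
    fit = sps.linregress(hu, rho)
    return CalibrationModel(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2), pairs=pairs)


def extract_phantom_pairs(volume: CTVolume, rois) -> list[tuple[float, float]]:
    """Mean HU in each phantom ROI paired with its nominal density."""
    return [(float(volume.values[r].mean()), float(rho)) for r, rho in rois]


def apply_calibration(volume: CTVolume, model: CalibrationModel) -> CTVolume:
    """Element-wise HU -> density conversion; geometry is preserved."""
    return CTVolume(values=model.slope * volume.values + model.intercept,
                    voxel_size=volume.voxel_size, mask=volume.mask)


# --------------------------------------------------------------------------
# ROI placement
# --------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def place_roi(volume: CTVolume, roi: RoiSpec = RoiSpec(),
              center: tuple[int, int] | None = None) -> tuple[slice, slice, slice]:
    """Centred ROI index ranges: in-plane window over the central slices.

    The in-plane window spans ``round(extent / voxel_size)`` voxels per axis
    (nearest integer, ties rounded up), centred on the specimen-mask centroid
    (or an explicit ``center``, or the volume centre).  The ``n_slices`` most
    central slices along z are selected.
    """
    nx, ny, nz = volume.values.shape
    win = [
        _round_half_up(roi.extent_mm[a] / volume.voxel_size[a]) for a in (0, 1)
    ]
    if roi.n_slices > nz:
        raise ValueError(f"requested {roi.n_slices} slices but volume has {nz}")

    if center is None:
        if volume.mask is not None and volume.mask.any():
            cx, cy, _ = (np.array(np.nonzero(volume.mask)).mean(axis=1))
            center = (int(round(cx)), int(round(cy)))
        else:
            center = (nx // 2, ny // 2)

    out = []
    for a, (c, w, n) in enumerate(zip(center, win, (nx, ny))):
        lo = c - w // 2
        hi = lo + w
        if lo < 0 or hi > n:
            raise ValueError(
                f"ROI window [{lo}, {hi}) exceeds volume bounds on axis {a}")
        out.append(slice(lo, hi))
    z0 = (nz - roi.n_slices) // 2
    out.append(slice(z0, z0 + roi.n_slices))
    return tuple(out)


# --------------------------------------------------------------------------
# Densitometry and binary morphometry
# --------------------------------------------------------------------------


def mean_bmd(density_volume: CTVolume, roi: tuple[slice, slice, slice]) -> float:
    """Arithmetic mean density over the ROI, mg/cm^3."""
    vals = density_volume.values[roi]
    if vals.size == 0:
        raise ValueError("ROI is empty")
    return float(vals.mean())


def binarize(density_volume: CTVolume, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Global threshold: a voxel is bone iff density >= threshold (inclusive)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return density_volume.values >= threshold


def bv_tv(binary_roi: np.ndarray) -> float:
    """Bone volume over total volume, %."""
    b = np.asarray(binary_roi, dtype=bool)
    if b.size == 0:
        raise ValueError("ROI is empty")
    return 100.0 * float(b.sum()) / b.size


def _runs_along_axis(binary: np.ndarray, axis: int) -> tuple[int, int]:
    """(bone voxel count, number of bone runs) along lines parallel to axis."""
    b = np.moveaxis(np.asarray(binary, dtype=bool), axis, -1)
    starts = b.copy()
    starts[..., 1:] &= ~b[..., :-1]   # wrap-free: a run starts at the line
    return int(b.sum()), int(starts.sum())   # start or after a marrow voxel


def mil_tbn(binary_roi: np.ndarray,
            voxel_size: tuple[float, float, float] = (0.23, 0.23, 0.6),
            directions: tuple[int, ...] = (0, 1, 2)) -> MilResult:
    """Mean intercept length of the bone phase and derived trabecular number.

    One test line per voxel row is cast along each requested axis.  For a
    direction d, MIL_d = (total bone phase length along the lines) divided by
    (number of bone intercepts), using physical voxel lengths so anisotropic
    voxels are handled.  Mean trabecular plate thickness Tb.Th* is the
    average MIL over the requested directions, and trabecular number follows
    from the plate-model identity TbN = (BV/TV) / Tb.Th*.
    """
    b = np.asarray(binary_roi, dtype=bool)
    if b.ndim != 3:
        raise ValueError("binary ROI must be 3-dimensional")
    if not b.any() or b.all():
        raise ValueError("MIL undefined: ROI must contain both bone and marrow")

    mil: dict[int, float] = {}
    lengths: dict[int, float] = {}
    counts: dict[int, int] = {}
    for d in directions:
        n_bone, n_runs = _runs_along_axis(b, d)
        if n_runs == 0:
            raise ValueError(f"no bone intercepts along axis {d}; MIL undefined")
        length = n_bone * voxel_size[d]
        mil[d] = length / n_runs
        lengths[d] = length
        counts[d] = n_runs

    tb_th = float(np.mean([mil[d] for d in directions]))
    bvtv_frac = float(b.sum()) / b.size
    return MilResult(mil_mm=mil, bone_length_mm=lengths, n_intercepts=counts,
                     tb_th_mm=tb_th, tbn=bvtv_frac / tb_th)


# --------------------------------------------------------------------------
# Fractal dimension
# --------------------------------------------------------------------------


def box_counts(binary_slice: np.ndarray, box_sizes=DEFAULT_BOX_SIZES) -> np.ndarray:
    """Occupied-box counts N(s) for each box side s (in pixels).

    The grid is anchored at the array origin; partial boxes at the borders
    are counted if they contain any bone pixel.
    """
    b = np.asarray(binary_slice, dtype=bool)
    if b.ndim != 2:
        raise ValueError("box counting operates on 2D slices")
    out = []
    for s in box_sizes:
        if s < 1:
            raise ValueError("box sizes must be >= 1")
        ny, nx = b.shape
        py = (-ny) % s
        px = (-nx) % s
        padded = np.pad(b, ((0, py), (0, px)))
        blocks = padded.reshape(padded.shape[0] // s, s, padded.shape[1] // s, s)
        out.append(int(blocks.any(axis=(1, 3)).sum()))
    return np.array(out)


def fractal_dimension(binary_slices, box_sizes=DEFAULT_BOX_SIZES) -> float:
    """Mean box-counting fractal dimension over 2D transverse slices.

    Per slice, FD is the least-squares slope of log N(s) versus log(1/s).
    Slices without any bone pixels are excluded with a warning; FD of a
    filled plane is exactly 2 and of a one-pixel line exactly 1 when the
    box sizes divide the image evenly.
    """
    sizes = np.asarray(box_sizes, dtype=float)
    if sizes.size < 3:
        raise ValueError("need at least three box sizes")
    fds = []
    skipped = 0
    for sl in binary_slices:
        sl = np.asarray(sl, dtype=bool)
        if not sl.any():
            skipped += 1
            continue
        n = box_counts(sl, box_sizes)
        slope = np.polyfit(np.log(1.0 / sizes), np.log(n), 1)[0]
        fds.append(slope)
    if skipped:
        warnings.warn(f"{skipped} slice(s) without bone excluded from FD",
                      RuntimeWarning)
    if not fds:
        raise ValueError("FD undefined: no slice contains bone")
    return float(np.mean(fds))


# --------------------------------------------------------------------------
# Cross-sectional areas
# --------------------------------------------------------------------------


def cross_sectional_areas(mask: np.ndarray,
                          voxel_size: tuple[float, float, float] = (0.23, 0.23, 0.6)
                          ) -> tuple[float, float]:
    """(mean, min) transverse cross-sectional area of the specimen, cm^2.

    Per-slice area is the in-plane pixel count times the pixel area; slices
    where the mask is empty are ignored.
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 3:
        raise ValueError("mask must be 3-dimensional")
    counts = m.sum(axis=(0, 1))
    nonempty = counts[counts > 0]
    if nonempty.size == 0:
        raise ValueError("mask is empty")
    pixel_area_cm2 = voxel_size[0] * voxel_size[1] / 100.0   # mm^2 -> cm^2
    areas = nonempty * pixel_area_cm2
    return float(areas.mean()), float(areas.min())


# --------------------------------------------------------------------------
# Per-specimen driver
# --------------------------------------------------------------------------


def analyze_volume(volume: CTVolume, phantom_pairs, roi: RoiSpec = RoiSpec(),
                   threshold: float = DEFAULT_THRESHOLD,
                   box_sizes=DEFAULT_BOX_SIZES,
                   mil_directions: tuple[int, ...] = (0, 1, 2),
                   center: tuple[int, int] | None = None) -> MorphometryResult:
    """Full morphometry chain on one HU volume with phantom calibration."""
    model = calibrate(phantom_pairs)
    density = apply_calibration(volume, model)
    roi_idx = place_roi(density, roi, center=center)
    bmd = mean_bmd(density, roi_idx)
    binary = binarize(density, threshold)[roi_idx]
    bvtv = bv_tv(binary)
    mil = mil_tbn(binary, volume.voxel_size, mil_directions)
    slices = [binary[:, :, k] for k in range(binary.shape[2])]
    fd = fractal_dimension(slices, box_sizes)
    if volume.mask is not None:
        mean_a, min_a = cross_sectional_areas(volume.mask, volume.voxel_size)
    else:
        mean_a = min_a = float("nan")
    return MorphometryResult(bmd=bmd, bv_tv=bvtv, tbn=mil.tbn, fd=fd,
                             mean_area=mean_a, min_area=min_a)
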