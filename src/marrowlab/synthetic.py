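"""Synthetic data generators with analytically known ground truth.

Every downstream stage of the pipeline (spectral fitting, CT morphometry,
failure-load detection, cohort statistics) is exercised against data produced
here, where the true PDFF, bone volume fraction, failure load and population
correlations are known exactly.

The generators emulate the in-vitro study conditions: four-echo STEAM
spectra (TE 12/15/20/25 ms, 4096 points, 5 kHz bandwidth, 3 T), CT volumes
at 0.23 x 0.23 x 0.6 mm voxels with an embedded density-calibration phantom,
softening load-displacement curves, and ten-specimen cohorts whose means,
SDs and cross-correlations default to the published summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fatmodel import (
    FAT_PPM,
    GROUP_OF_PPM,
    GROUPS,
    WATER_PPM,
    TriglycerideComposition,
)
from .mrs import Spectrum, _FWHM_TO_SIGMA, _SQRT2PI

# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------


@dataclass
class SpectrumGenSpec:
    """Forward model of a multi-echo marrow spectrum acquisition."""

    pdff_true: float = 0.32
    te_list: tuple[float, ...] = (12.0, 15.0, 20.0, 25.0)   # ms
    t2_fat: float = 80.0       # ms
    t2_water: float = 25.0     # ms
    linewidth_fat: float = 30.0            # Hz FWHM, shared by fat peaks
    linewidth_water_narrow: float = 30.0   # Hz
    linewidth_water_broad: float = 150.0   # Hz
    broad_water_fraction: float = 0.2      # of total water area
    snr: float = np.inf        # peak-B amplitude at shortest TE / noise SD
    field_strength: float = 3.0    # T
    n_points: int = 4096
    bandwidth: float = 5000.0      # Hz
    composition: TriglycerideComposition = field(default_factory=TriglycerideComposition)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.pdff_true <= 1.0:
            raise ValueError("pdff_true must lie in [0, 1]")
        te = np.asarray(self.te_list, dtype=float)
        if te.size == 0 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("te_list must be nonempty, positive and strictly increasing")
        for name in ("t2_fat", "t2_water", "linewidth_fat",
                     "linewidth_water_narrow", "linewidth_water_broad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.broad_water_fraction < 1.0:
            raise ValueError("broad_water_fraction must lie in [0, 1)")
        if self.n_points < 256:
            raise ValueError("n_points must be at least 256")
        if self.snr <= 0:
            raise ValueError("snr must be positive (use inf for noiseless)")


@dataclass
class SpectrumTruth:
    """Generating parameters of a spectrum set, for oracle comparisons."""

    pdff_true: float
    group_areas_te0: dict[str, float]
    area_water_narrow_te0: float
    area_water_broad_te0: float
    t2_fat: float
    t2_water: float
    constraint_ratios: tuple[float, float]
    noiseless_real: list[np.ndarray]   # one noise-free template per TE


def generate_spectrum(spec: SpectrumGenSpec) -> tuple[list[Spectrum], SpectrumTruth]:
    """Simulate one multi-echo spectrum set.

    The total TE=0 fat area is ``pdff_true`` and the narrow-water area
    ``1 - pdff_true`` (arbitrary common scale), distributed over the nine
    fat resonances by the triglyceride proton weights.  Group areas decay
    as exp(-TE/T2) with the fat or water T2.  Complex white Gaussian noise
    is added with SD set by ``snr`` against the tallest fat peak (1.30 ppm)
    at the shortest echo.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    fat_total = spec.pdff_true
    water_narrow = 1.0 - spec.pdff_true
    bwf = spec.broad_water_fraction
    water_broad = water_narrow * bwf / (1.0 - bwf)

    rel = spec.composition.group_areas()
    rel_total = sum(rel.values())
    group_te0 = {g: fat_total * rel[g] / rel_total for g in GROUPS}
    weights = spec.composition.within_group_weights()

    # ppm axis, descending, carrier on water
    df = spec.bandwidth / spec.n_points
    hz_off = (spec.n_points / 2.0 - np.arange(spec.n_points)) * df
    hz_per_ppm = spec.field_strength * 42.577
    ppm = WATER_PPM + hz_off / hz_per_ppm

    sigma_fat = spec.linewidth_fat * _FWHM_TO_SIGMA
    sigma_wn = spec.linewidth_water_narrow * _FWHM_TO_SIGMA
    sigma_wb = spec.linewidth_water_broad * _FWHM_TO_SIGMA

    def build(te: float) -> np.ndarray:
        decay_f = np.exp(-te / spec.t2_fat)
        decay_w = np.exp(-te / spec.t2_water)
        out = np.zeros_like(ppm)
        for p0 in FAT_PPM:
            area = group_te0[GROUP_OF_PPM[p0]] * weights[p0] * decay_f
            if area == 0.0:
                continue
            center = p0 * hz_per_ppm
            out += area / (sigma_fat * _SQRT2PI) * np.exp(
                -0.5 * ((ppm * hz_per_ppm - center) / sigma_fat) ** 2)
        for area0, sigma in ((water_narrow, sigma_wn), (water_broad, sigma_wb)):
            area = area0 * decay_w
            if area == 0.0:
                continue
            center = WATER_PPM * hz_per_ppm
            out += area / (sigma * _SQRT2PI) * np.exp(
                -0.5 * ((ppm * hz_per_ppm - center) / sigma) ** 2)
        return out

    templates = [build(te) for te in spec.te_list]

    te_min = spec.te_list[0]
    peak_b_amp = (group_te0["B"] * weights[1.30] * np.exp(-te_min / spec.t2_fat)
                  / (sigma_fat * _SQRT2PI))
    noise_sd = 0.0 if np.isinf(spec.snr) else peak_b_amp / spec.snr

    spectra = []
    for te, template in zip(spec.te_list, templates):
        signal = template.astype(complex)
        if noise_sd > 0:
            signal = signal + noise_sd * (
                rng.standard_normal(spec.n_points)
                + 1j * rng.standard_normal(spec.n_points))
        spectra.append(Spectrum(ppm=ppm.copy(), signal=signal, te=te,
                                field_strength=spec.field_strength,
                                bandwidth=spec.bandwidth))

    if fat_total + water_narrow > 0:
        pdff_check = fat_total / (fat_total + water_narrow)
        assert abs(pdff_check - spec.pdff_true) < 1e-12

    truth = SpectrumTruth(
        pdff_true=spec.pdff_true,
        group_areas_te0=group_te0,
        area_water_narrow_te0=water_narrow,
        area_water_broad_te0=water_broad,
        t2_fat=spec.t2_fat,
        t2_water=spec.t2_water,
        constraint_ratios=spec.composition.constraint_ratios(),
        noiseless_real=templates,
    )
    return spectra, truth


# --------------------------------------------------------------------------
# CT volumes
# --------------------------------------------------------------------------


@dataclass
class LatticeSpec:
    """Axis-aligned trabecular lattice: plates or rods.

    ``axis`` is the plate normal for plates, or the rod direction for rods.
    Thickness and spacing are in mm; they must each cover at least one voxel
    along the relevant axes unless ``allow_subvoxel``.
    """

    kind: str = "plate"          # "plate" | "rod"
    thickness_mm: float = 0.23
    spacing_mm: float = 0.69
    axis: int = 0


@dataclass
class VolumeGenSpec:
    """Forward model of a calibrated CT acquisition of a trabecular cube."""

    shape: tuple[int, int, int] = (64, 64, 24)
    voxel_size: tuple[float, float, float] = (0.23, 0.23, 0.6)   # mm
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    bone_density: float = 400.0     # mg/cm^3 hydroxyapatite equivalent
    marrow_density: float = 50.0
    phantom_densities: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0)
    calibration_slope: float = 1.0        # mg/cm^3 per HU
    calibration_intercept: float = 0.0    # mg/cm^3
    noise_sd_hu: float = 0.0
    phantom_rows: int = 6      # strip of voxels along y reserved for the phantom
    allow_subvoxel: bool = False
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(n < 1 for n in self.shape):
            raise ValueError("shape must be positive")
        pd_ = np.asarray(self.phantom_densities, dtype=float)
        if pd_.size < 2 or np.any(np.diff(pd_) <= 0):
            raise ValueError("phantom_densities must be strictly increasing, length >= 2")
        if self.calibration_slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if self.lattice.kind not in ("plate", "rod"):
            raise ValueError("lattice kind must be 'plate' or 'rod'")


@dataclass
class VolumeTruth:
    """Exact ground truth of a generated volume."""

    bone_mask: np.ndarray          # over the lattice region
    lattice_region: tuple[slice, slice, slice]
    bv_tv_pct: float               # exact voxel count on the lattice region
    expected_mil_mm: dict[int, float | None]   # per axis; None if no closed form
    phantom_rois: list[tuple[tuple[slice, slice, slice], float]]
    calibration_slope: float
    calibration_intercept: float


def _periodic_on(thickness_mm: float, spacing_mm: float, voxel_mm: float,
                 n: int, allow_subvoxel: bool) -> tuple[np.ndarray, int]:
    t_vox = thickness_mm / voxel_mm
    s_vox = spacing_mm / voxel_mm
    if (t_vox < 1.0 - 1e-9 or s_vox < 1.0 - 1e-9) and not allow_subvoxel:
        raise ValueError(
            "lattice thickness/spacing below one voxel; ground truth is undefined "
            "under discretization (set allow_subvoxel to override)")
    t = max(int(round(t_vox)), 1)
    s = max(int(round(s_vox)), 1)
    return (np.arange(n) % (t + s)) < t, t


def _lattice_mask(spec: VolumeGenSpec, region_shape: tuple[int, int, int]) -> np.ndarray:
    lat = spec.lattice
    ax = lat.axis
    if lat.kind == "plate":
        # plates are periodic along their normal axis
        on, _ = _periodic_on(lat.thickness_mm, lat.spacing_mm,
                             spec.voxel_size[ax], region_shape[ax],
                             spec.allow_subvoxel)
        shape1 = [1, 1, 1]
        shape1[ax] = region_shape[ax]
        return np.broadcast_to(on.reshape(shape1), region_shape).copy()
    # rods along `axis`: periodic in the two transverse axes
    trans = [a for a in range(3) if a != ax]
    parts = []
    for a in trans:
        on, _ = _periodic_on(lat.thickness_mm, lat.spacing_mm,
                             spec.voxel_size[a], region_shape[a],
                             spec.allow_subvoxel)
        sh = [1, 1, 1]
        sh[a] = region_shape[a]
        parts.append(np.broadcast_to(on.reshape(sh), region_shape))
    return (parts[0] & parts[1]).copy()


def generate_volume(spec: VolumeGenSpec):
    """Simulate a calibrated CT volume: lattice + phantom, encoded in HU.

    Densities (mg/cm^3) are mapped to HU by inverting the configured affine
    calibration, so recovering the calibration from the phantom rods and
    applying it reproduces the density field (up to the optional HU noise).

    Returns ``(CTVolume, VolumeTruth)``.
    """
    from .morphometry import CTVolume   # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape

    n_phantom_rows = spec.phantom_rows if ny > spec.phantom_rows + 4 else 0
    lattice_region = (slice(0, nx), slice(n_phantom_rows, ny), slice(0, nz))
    region_shape = (nx, ny - n_phantom_rows, nz)

    mask = _lattice_mask(spec, region_shape)
    density = np.full(spec.shape, spec.marrow_density, dtype=float)
    region = density[lattice_region]
    region[mask] = spec.bone_density
    density[lattice_region] = region

    phantom_rois: list[tuple[tuple[slice, slice, slice], float]] = []
    if n_phantom_rows:
        k = len(spec.phantom_densities)
        block = nx // k
        for i, rho in enumerate(spec.phantom_densities):
            x0 = i * block + max(block // 4, 1)
            x1 = min((i + 1) * block - max(block // 4, 1), nx)
            roi = (slice(x0, max(x1, x0 + 1)), slice(1, n_phantom_rows - 1), slice(0, nz))
            density[roi] = rho
            phantom_rois.append((roi, rho))

    hu = (density - spec.calibration_intercept) / spec.calibration_slope
    if spec.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)

    bv_tv = 100.0 * mask.sum() / mask.size

    lat = spec.lattice
    expected_mil: dict[int, float | None] = {0: None, 1: None, 2: None}
    if lat.kind == "plate":
        t = max(int(round(lat.thickness_mm / spec.voxel_size[lat.axis])), 1)
        expected_mil[lat.axis] = t * spec.voxel_size[lat.axis]
        for a in range(3):
            if a != lat.axis:
                # lines parallel to the plates never leave the bone phase
                expected_mil[a] = region_shape[a] * spec.voxel_size[a]

    truth = VolumeTruth(
        bone_mask=mask,
        lattice_region=lattice_region,
        bv_tv_pct=float(bv_tv),
        expected_mil_mm=expected_mil,
        phantom_rois=phantom_rois,
        calibration_slope=spec.calibration_slope,
        calibration_intercept=spec.calibration_intercept,
    )
    return CTVolume(values=hu, voxel_size=spec.voxel_size), truth


# --------------------------------------------------------------------------
# Load-displacement curves
# --------------------------------------------------------------------------


def generate_load_curve(fl_true: float, drop_fraction: float = 0.3,
                        n_points: int = 200, seed: int = 0,
                        noise_sd: float = 0.0, secondary_rise: float = 0.9):
    """Piecewise-linear compression curve with a controlled post-peak drop.

    The curve rises monotonically to ``fl_true``, falls by ``drop_fraction``
    of the peak, then rises again to ``secondary_rise * fl_true`` at the end
    of the record.  On the noiseless curve, the first-peak/drop->10% rule
    returns ``fl_true`` exactly when ``drop_fraction > 0.1`` and detects no
    failure otherwise.

    Returns a :class:`~marrowlab.biomech.LoadCurve`.
    """
    from .biomech import LoadCurve

    if fl_true <= 0:
        raise ValueError("fl_true must be positive")
    if not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in (0, 1)")
    if n_points < 10:
        raise ValueError("n_points must be at least 10")

    rng = np.random.default_rng(seed)
    n_rise = n_points // 2
    n_drop = n_points // 4
    n_tail = n_points - n_rise - n_drop

    load = np.concatenate([
        np.linspace(0.0, fl_true, n_rise),
        np.linspace(fl_true, fl_true * (1.0 - drop_fraction), n_drop + 1)[1:],
        np.linspace(fl_true * (1.0 - drop_fraction), fl_true * secondary_rise,
                    n_tail + 1)[1:],
    ])
    displacement = np.linspace(0.0, 3.0, n_points)   # mm, monotone ramp
    if noise_sd > 0:
        jitter = rng.normal(0.0, noise_sd, size=n_points)
        jitter[n_rise - 1] = 0.0   # keep the true peak value intact
        load = load + jitter
    return LoadCurve(displacement=displacement, load=load)


# --------------------------------------------------------------------------
# Specimen cohorts
# --------------------------------------------------------------------------

COHORT_VARIABLES: tuple[str, ...] = (
    "fat_fraction",   # %
    "bmd",            # mg/cm^3
    "bv_tv",          # %
    "tbn",            # mm^-1
    "fd",             # dimensionless
    "norm_fl",        # N/cm^2
    "min_area",       # cm^2
    "mean_area",      # cm^2
)

DEFAULT_COHORT_MEANS: dict[str, float] = {
    "fat_fraction": 32.0,
    "bmd": 121.5,
    "bv_tv": 38.8,
    "tbn": 1.13,
    "fd": 1.57,
    "norm_fl": 442.0,
    "min_area": 5.8,
    "mean_area": 6.5,
}

DEFAULT_COHORT_SDS: dict[str, float] = {
    "fat_fraction": 5.0,
    "bmd": 34.3,
    "bv_tv": 10.8,
    "tbn": 0.11,
    "fd": 0.07,
    "norm_fl": 251.0,
    "min_area": 1.4,
    "mean_area": 1.5,
}


def default_cohort_correlation() -> np.ndarray:
    """Default cross-correlation structure of the cohort variables.

    Fat fraction is negatively correlated with bone quantity/quality and
    strength; normalized failure load is strongly positively correlated with
    the CT parameters.  Correlations among the CT parameters themselves and
    between the two area measures are set to values typical of trabecular
    bone; vertebral size is taken as independent of density and marrow fat.
    """
    names = list(COHORT_VARIABLES)
    corr = np.eye(len(names))

    def put(a: str, b: str, v: float) -> None:
        i, j = names.index(a), names.index(b)
        corr[i, j] = corr[j, i] = v

    put("fat_fraction", "norm_fl", -0.77)
    put("fat_fraction", "bmd", -0.72)
    put("fat_fraction", "bv_tv", -0.64)
    put("fat_fraction", "tbn", -0.62)
    put("fat_fraction", "fd", -0.36)
    put("norm_fl", "bmd", 0.90)
    put("norm_fl", "bv_tv", 0.88)
    put("norm_fl", "tbn", 0.89)
    put("norm_fl", "fd", 0.83)
    put("bmd", "bv_tv", 0.85)
    put("bmd", "tbn", 0.80)
    put("bmd", "fd", 0.70)
    put("bv_tv", "tbn", 0.90)
    put("bv_tv", "fd", 0.75)
    put("tbn", "fd", 0.80)
    put("min_area", "mean_area", 0.90)
    return corr


@dataclass
class CohortGenSpec:
    """Multivariate-normal specimen cohort with configurable correlations."""

    n_specimens: int = 10
    means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COHORT_MEANS))
    sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COHORT_SDS))
    correlation: np.ndarray = field(default_factory=default_cohort_correlation)
    seed: int = 0

    def validate(self) -> None:
        if self.n_specimens < 3:
            raise ValueError("n_specimens must be at least 3")
        for v in COHORT_VARIABLES:
            if v not in self.means or v not in self.sds:
                raise ValueError(f"means/sds must cover variable {v!r}")
            if self.sds[v] < 0:
                raise ValueError("SDs must be non-negative")
        c = np.asarray(self.correlation, dtype=float)
        k = len(COHORT_VARIABLES)
        if c.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}")
        if not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(c)
        if w.min() < -1e-10:
            raise ValueError(
                f"correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {w.min():.3e})")


def generate_cohort(spec: CohortGenSpec) -> tuple[pd.DataFrame, CohortGenSpec]:
    """Draw a specimen cohort from the configured multivariate normal.

    The Gaussian model reflects the observation that none of the measured
    parameters departed significantly from normality in the source cohort.
    The absolute failure load ``fl`` is derived as ``norm_fl * min_area``
    so the table is internally consistent.

    Returns the cohort table and the generating spec (the ground truth).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    names = list(COHORT_VARIABLES)
    mu = np.array([spec.means[v] for v in names])
    sd = np.array([spec.sds[v] for v in names])
    corr = np.asarray(spec.correlation, dtype=float)

    # Factor via eigen-decomposition so degenerate (zero-SD / singular
    # correlation) cases are handled exactly.
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    z = rng.standard_normal((spec.n_specimens, len(names)))
    x = mu + (z @ factor.T) * sd

    df = pd.DataFrame(x, columns=names)
    df.insert(0, "specimen_id", [f"S{i + 1:02d}" for i in range(spec.n_specimens)])
    df["fl"] = df["norm_fl"] * df["min_area"]
    return df, spec
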