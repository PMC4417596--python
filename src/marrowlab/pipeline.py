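"""End-to-end orchestration: simulate -> fit -> morphometry -> failure load -> stats.

A pipeline run draws a specimen cohort with known ground truth, simulates the
three measurement modalities for every specimen (multi-echo spectra, a
calibrated CT volume with specimen mask, a compression curve), re-measures
each quantity with the package's analysis chain, and then produces a
mean +/- SD summary table and the pairwise regression/bootstrap table from
the measured values.  All randomness derives from one global seed, from
which per-stage, per-specimen seeds are split deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomech import detect_failure_load
from .morphometry import (
    CTVolume,
    RoiSpec,
    analyze_volume,
    extract_phantom_pairs,
)
from .mrs import estimate_pdff
from .stats import build_regression_table
from .synthetic import (
    COHORT_VARIABLES,
    CohortGenSpec,
    LatticeSpec,
    SpectrumGenSpec,
    VolumeGenSpec,
    generate_cohort,
    generate_load_curve,
    generate_spectrum,
    generate_volume,
)


@dataclass
class RunConfig:
    """Configuration of a full synthetic-cohort pipeline run."""

    seed: int = 0
    n_specimens: int = 10
    te_list: tuple[float, ...] = (12.0, 15.0, 20.0, 25.0)   # ms
    snr: float = 50.0              # spectral amplitude SNR; inf = noiseless
    t2_fat: float = 80.0           # ms
    t2_water: float = 25.0         # ms
    volume_shape: tuple[int, int, int] = (144, 156, 24)
    voxel_size: tuple[float, float, float] = (0.23, 0.23, 0.6)   # mm
    threshold: float = 200.0       # mg/cm^3
    roi: RoiSpec = field(default_factory=RoiSpec)
    lattice_period_vox: int = 5    # plate period used to realise target BV/TV
    noise_sd_hu: float = 0.0
    drop_fraction: float = 0.3     # post-peak drop of the simulated curves
    n_boot: int = 1000
    p_method: str = "sign"
    fractional_units: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi"] = dataclasses.asdict(self.roi)
        return _jsonable(d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _stage_seeds(seed: int, n_specimens: int) -> dict[str, np.ndarray]:
    """Deterministic per-stage, per-specimen seeds from one global seed."""
    state = np.random.SeedSequence(seed).generate_state(2 + 3 * n_specimens) % (2**31)
    return {
        "cohort": int(state[0]),
        "stats": int(state[1]),
        "spectra": state[2:2 + n_specimens].astype(int),
        "volumes": state[2 + n_specimens:2 + 2 * n_specimens].astype(int),
        "curves": state[2 + 2 * n_specimens:].astype(int),
    }


def _clip_physical(truth: pd.DataFrame) -> pd.DataFrame:
    """Clamp drawn cohort values to physically meaningful ranges.

    The unbounded Gaussian cohort model can produce non-physical draws
    (negative strength, vanishing areas) at small n; the measurement
    simulators require positive inputs, so the generating values are
    truncated at loose physical floors before simulation.  The clipped
    values are what the ``*_true`` columns report.
    """
    t = truth.copy()
    t["fat_fraction"] = t["fat_fraction"].clip(0.5, 99.5)
    t["bv_tv"] = t["bv_tv"].clip(5.0, 95.0)
    t["min_area"] = t["min_area"].clip(lower=1.0)
    t["mean_area"] = np.maximum(t["mean_area"], t["min_area"])
    t["norm_fl"] = t["norm_fl"].clip(lower=10.0)
    t["fl"] = t["norm_fl"] * t["min_area"]
    return t


def _specimen_mask(shape: tuple[int, int, int], voxel_size, min_area: float,
                   mean_area: float, y_offset: int) -> np.ndarray:
    """Per-slice centred squares whose areas ramp from the min upward.

    Slice areas are linearly spaced between ``min_area`` and
    ``2 * mean_area - min_area`` so the mask's minimum and mean transverse
    areas approximate the requested values (up to pixel quantisation).
    """
    nx, ny, nz = shape
    areas = np.linspace(min_area, max(2 * mean_area - min_area, min_area), nz)
    mask = np.zeros(shape, dtype=bool)
    cx = nx // 2
    cy = y_offset + (ny - y_offset) // 2
    pixel_mm = voxel_size[0]
    for k, a_cm2 in enumerate(areas):
        side = int(round(np.sqrt(a_cm2 * 100.0) / pixel_mm))
        side = max(min(side, nx - 2, ny - y_offset - 2), 1)
        x0, y0 = cx - side // 2, cy - side // 2
        mask[x0:x0 + side, y0:y0 + side, k] = True
    return mask


def _simulate_specimen_volume(truth_row: pd.Series, config: RunConfig,
                              seed: int) -> CTVolume:
    """CT volume realising (approximately) one specimen's target morphometry."""
    period = config.lattice_period_vox
    f_target = float(np.clip(truth_row["bv_tv"], 5.0, 95.0)) / 100.0
    t_vox = int(np.clip(round(f_target * period), 1, period - 1))
    f_actual = t_vox / period

    # Choose phase densities so the ROI mean density matches the target BMD
    # while bone stays above and marrow below the segmentation threshold.
    bone = 400.0
    marrow = (truth_row["bmd"] - f_actual * bone) / (1.0 - f_actual)
    if marrow >= config.threshold - 20.0:
        marrow = config.threshold - 20.0
    vx = config.voxel_size[0]
    spec = VolumeGenSpec(
        shape=config.volume_shape,
        voxel_size=config.voxel_size,
        lattice=LatticeSpec(kind="plate", thickness_mm=t_vox * vx,
                            spacing_mm=(period - t_vox) * vx, axis=0),
        bone_density=bone,
        marrow_density=float(marrow),
        calibration_slope=0.8, calibration_intercept=-5.0,
        noise_sd_hu=config.noise_sd_hu,
        seed=seed,
    )
    volume, vtruth = generate_volume(spec)
    volume.mask = _specimen_mask(config.volume_shape, config.voxel_size,
                                 float(truth_row["min_area"]),
                                 float(truth_row["mean_area"]),
                                 y_offset=spec.phantom_rows)
    volume.phantom_rois = vtruth.phantom_rois   # carried for calibration
    return volume


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages in dependency order and write the output tables.

    Outputs in ``out_dir``: ``cohort.csv`` (measured and true values per
    specimen), ``summary.csv`` (mean +/- SD per measured variable),
    ``regressions.csv`` (pairwise OLS + bootstrap), and ``manifest.json``.
    The manifest is written on failure as well, recording the failed stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "status": "running",
        "stage": None,
        "outputs": {},
    }
    try:
        seeds = _stage_seeds(config.seed, config.n_specimens)

        manifest["stage"] = "cohort"
        truth, _ = generate_cohort(CohortGenSpec(n_specimens=config.n_specimens,
                                                 seed=seeds["cohort"]))
        truth = _clip_physical(truth)

        rows = []
        for i in range(config.n_specimens):
            t = truth.iloc[i]

            manifest["stage"] = f"mrs[{i}]"
            pdff_true = float(np.clip(t["fat_fraction"] / 100.0, 0.005, 0.995))
            spectra, _ = generate_spectrum(SpectrumGenSpec(
                pdff_true=pdff_true, te_list=config.te_list,
                t2_fat=config.t2_fat, t2_water=config.t2_water,
                snr=config.snr, seed=int(seeds["spectra"][i])))
            t2res, _ = estimate_pdff(spectra)

            manifest["stage"] = f"morphometry[{i}]"
            volume = _simulate_specimen_volume(t, config, int(seeds["volumes"][i]))
            pairs = extract_phantom_pairs(volume, volume.phantom_rois)
            # The synthetic lattice is plates normal to x; the plate-parallel
            # directions are degenerate for MIL (lines never leave the bone
            # phase), so TbN uses the normal direction only.
            morpho = analyze_volume(volume, pairs, roi=config.roi,
                                    threshold=config.threshold,
                                    mil_directions=(0,))

            manifest["stage"] = f"biomech[{i}]"
            curve = generate_load_curve(fl_true=float(t["fl"]),
                                        drop_fraction=config.drop_fraction,
                                        seed=int(seeds["curves"][i]))
            failure = detect_failure_load(curve, min_area=morpho.min_area)
            fl = failure.failure_load if failure.detected else np.nan
            norm_fl = (failure.normalized_failure_load
                       if failure.detected else np.nan)

            rows.append({
                "specimen_id": t["specimen_id"],
                "fat_fraction": 100.0 * t2res.pdff,
                "bmd": morpho.bmd,
                "bv_tv": morpho.bv_tv,
                "tbn": morpho.tbn,
                "fd": morpho.fd,
                "norm_fl": norm_fl,
                "min_area": morpho.min_area,
                "mean_area": morpho.mean_area,
                "fl": fl,
                "t2_fat_ms": t2res.t2_fat,
                "t2_water_ms": t2res.t2_water,
                **{f"{v}_true": float(t[v]) for v in COHORT_VARIABLES},
                "fl_true": float(t["fl"]),
                "pdff_true": pdff_true,
            })
        cohort = pd.DataFrame(rows)

        manifest["stage"] = "summary"
        summary = summarize_cohort(cohort[[*COHORT_VARIABLES, "fl"]])

        manifest["stage"] = "stats"
        regressions = build_regression_table(
            cohort, seed=seeds["stats"], n_boot=config.n_boot,
            fractional_units=config.fractional_units, p_method=config.p_method)

        manifest["stage"] = "write"
        paths = {
            "cohort": out / "cohort.csv",
            "summary": out / "summary.csv",
            "regressions": out / "regressions.csv",
        }
        cohort.to_csv(paths["cohort"], index=False)
        summary.to_csv(paths["summary"], index=False)
        regressions.to_csv(paths["regressions"], index=False)
        manifest["outputs"] = {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in paths.items()
        }
        manifest["status"] = "ok"
        manifest["stage"] = None
        return {"cohort": cohort, "summary": summary,
                "regressions": regressions, "manifest": manifest}
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = repr(exc)
        raise
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-variable mean and sample SD (n-1 denominator) of the cohort."""
    numeric = cohort.select_dtypes(include=[np.number])
    if len(numeric) < 2:
        raise ValueError("summary needs at least two specimens (SD undefined)")
    return pd.DataFrame({
        "variable": numeric.columns,
        "mean": numeric.mean().to_numpy(),
        "sd": numeric.std(ddof=1).to_numpy(),
        "n": len(numeric),
    })


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
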