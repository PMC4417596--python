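"""File formats: spectra (CSV + JSON sidecar), volumes (NIfTI), curves/cohorts (CSV)."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .biomech import LoadCurve
from .morphometry import CTVolume
from .mrs import Spectrum


def write_spectrum(spectrum: Spectrum, path: str | Path, tr_s: float = 6.0) -> None:
    """One spectrum as `<path>.csv` (ppm, real, imag) + `<path>.json` sidecar."""
    path = Path(path)
    sig = np.asarray(spectrum.signal, dtype=complex)
    df = pd.DataFrame({"ppm": spectrum.ppm, "real": sig.real, "imag": sig.imag})
    df.to_csv(path.with_suffix(".csv"), index=False)
    meta = {
        "te_ms": spectrum.te,
        "tr_s": tr_s,
        "field_strength_t": spectrum.field_strength,
        "bandwidth_hz": spectrum.bandwidth,
        "n_points": int(spectrum.ppm.size),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    df = pd.read_csv(path.with_suffix(".csv"))
    meta = json.loads(path.with_suffix(".json").read_text())
    signal = df["real"].to_numpy() + 1j * df["imag"].to_numpy()
    return Spectrum(ppm=df["ppm"].to_numpy(), signal=signal, te=meta["te_ms"],
                    field_strength=meta["field_strength_t"],
                    bandwidth=meta["bandwidth_hz"])


def read_spectrum_set(directory: str | Path) -> list[Spectrum]:
    """All spectra in a directory, sorted by echo time."""
    directory = Path(directory)
    spectra = [read_spectrum(p.with_suffix("")) for p in sorted(directory.glob("*.csv"))]
    if not spectra:
        raise FileNotFoundError(f"no spectra found in {directory}")
    return sorted(spectra, key=lambda s: s.te)


def write_volume(volume: CTVolume, path: str | Path) -> None:
    affine = np.diag(list(volume.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))


def read_volume(path: str | Path, mask_path: str | Path | None = None) -> CTVolume:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    mask = None
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0.5
    return CTVolume(values=np.asarray(img.get_fdata()), voxel_size=voxel_size,
                    mask=mask)


def write_load_curve(curve: LoadCurve, path: str | Path) -> None:
    pd.DataFrame({"displacement_mm": curve.displacement,
                  "load_N": curve.load}).to_csv(path, index=False)


def read_load_curve(path: str | Path) -> LoadCurve:
    df = pd.read_csv(path)
    return LoadCurve(displacement=df["displacement_mm"].to_numpy(),
                     load=df["load_N"].to_numpy())


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
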