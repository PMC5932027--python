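"""File contracts between pipeline stages.

Echo stacks, R2* maps and ROI masks travel as NIfTI; EPR spectra and IRM
curves as two-column CSV tables with a JSON sidecar holding the acquisition
metadata (frequency, temperature, masses, noise floor); cohort tables as
one-row-per-subject CSV.  Native Bruker (BES3T/ESP) spectrometer formats are
out of scope; convert to two-column text first.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .epr import EPRSpectrum
from .magnetometry import DEFAULT_NOISE_FLOOR_EMU, IRMCurve
from .relaxometry import MultiEchoStack, R2StarMap

_AFFINE = np.eye(4)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" \
        else path


def save_echo_stack(path: str | Path, stack: MultiEchoStack) -> None:
    """Write a multi-echo stack as NIfTI (echoes on the last axis) plus a
    JSON sidecar with echo times and voxel size."""
    path = Path(path)
    data = np.moveaxis(stack.data, 0, -1)
    nib.save(nib.Nifti1Image(data, _AFFINE), path)
    meta = {"te_ms": list(map(float, stack.te_ms)),
            "voxel_size_um": stack.voxel_size_um}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_echo_stack(path: str | Path) -> MultiEchoStack:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(_sidecar(path).read_text())
    data = np.moveaxis(np.asarray(img.dataobj, float), -1, 0)
    return MultiEchoStack(te_ms=np.asarray(meta["te_ms"]), data=data,
                          voxel_size_um=meta.get("voxel_size_um", 100.0))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _AFFINE), Path(path))


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(Path(path)).dataobj) > 0


def save_r2star_map(path: str | Path, r2map: R2StarMap) -> None:
    """R2* map, prefactor and validity mask as one 3-volume NIfTI."""
    stacked = np.stack([r2map.r2star, r2map.prefactor,
                        r2map.valid.astype(float)], axis=-1)
    nib.save(nib.Nifti1Image(stacked, _AFFINE), Path(path))


def save_spectrum(path: str | Path, spectrum: EPRSpectrum) -> None:
    path = Path(path)
    pd.DataFrame({"field_mT": spectrum.field_mt,
                  "amplitude": spectrum.amplitude}).to_csv(path, index=False)
    meta = {"frequency_ghz": spectrum.frequency_ghz,
            "modulation_gpp": spectrum.modulation_gpp,
            "temperature_k": spectrum.temperature_k,
            "sample_mass_g": spectrum.sample_mass_g}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_spectrum(path: str | Path) -> EPRSpectrum:
    path = Path(path)
    tab = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    field = tab.iloc[:, 0].to_numpy(float)
    if "gauss" in tab.columns[0].lower() or tab.columns[0].endswith("_G"):
        field = field / 10.0  # gauss accepted on input; mT internally
    return EPRSpectrum(field_mt=field,
                       amplitude=tab.iloc[:, 1].to_numpy(float),
                       frequency_ghz=meta["frequency_ghz"],
                       modulation_gpp=meta.get("modulation_gpp", 6.0),
                       temperature_k=meta.get("temperature_k", 12.0),
                       sample_mass_g=meta.get("sample_mass_g"))


def save_irm(path: str | Path, curve: IRMCurve) -> None:
    path = Path(path)
    pd.DataFrame({"field_G": curve.field,
                  "moment_emu_per_g": curve.moment}).to_csv(path, index=False)
    meta = {"temperature_k": curve.temperature_k,
            "dry_mass_g": curve.dry_mass_g,
            "noise_floor_emu": curve.noise_floor_emu}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_irm(path: str | Path) -> IRMCurve:
    path = Path(path)
    tab = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    unit = "T" if tab.columns[0].endswith("_T") else "G"
    return IRMCurve(field=tab.iloc[:, 0].to_numpy(float),
                    moment=tab.iloc[:, 1].to_numpy(float),
                    temperature_k=meta["temperature_k"],
                    dry_mass_g=meta["dry_mass_g"],
                    field_unit=unit,
                    noise_floor_emu=meta.get("noise_floor_emu",
                                             DEFAULT_NOISE_FLOOR_EMU))


def save_cohort(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(Path(path), index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
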