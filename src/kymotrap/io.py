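"""File formats and run configuration.

Native kymograph interchange is a multi-page TIFF (one page per channel)
with a JSON sidecar carrying timing, geometry and — for synthetic scenes
— the generator ground truth. An HDF5 dialect mirrors the instrument
export layout (/kymo/{green,red}, /kymo/line_time_s, /kymo/pixel_size_nm,
/force/{t,F}). Curves, trajectories and dwell samples travel as CSV with
named header columns.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional, Union

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .structures import ForceExtensionCurve, ForceTrace, Kymograph, Trajectory

__all__ = [
    "write_kymograph",
    "read_kymograph",
    "write_kymograph_hdf5",
    "curve_to_csv",
    "curve_from_csv",
    "trajectories_to_csv",
    "trajectories_from_csv",
    "dwells_to_csv",
    "dwells_from_csv",
    "RunConfig",
    "DEFAULT_CONFIG",
]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_kymograph(kymo: Kymograph, path: Union[str, Path]) -> Path:
    """Write a kymograph as multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    channels = list(kymo.counts)
    stack = np.stack([kymo.counts[ch] for ch in channels])
    tifffile.imwrite(path, stack)
    sidecar = {
        "line_time_s": kymo.line_time,
        "pixel_size_nm": kymo.pixel_size,
        "channels": channels,
        "saturation_level": kymo.saturation_level,
        "metadata": _jsonable(kymo.metadata),
    }
    if kymo.force is not None:
        sidecar["force"] = {
            "t": kymo.force.time.tolist(),
            "F": kymo.force.force.tolist(),
            "setpoint": kymo.force.setpoint,
        }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def _read_kymograph_tiff(path: Path) -> Kymograph:
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    for field in ("line_time_s", "pixel_size_nm", "channels"):
        if field not in sidecar:
            raise KeyError(f"kymograph sidecar is missing required field {field!r}")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = sidecar["channels"]
    if len(channels) != stack.shape[0]:
        raise ValueError(
            f"sidecar lists {len(channels)} channels but the TIFF has {stack.shape[0]} pages"
        )
    force = None
    if "force" in sidecar:
        force = ForceTrace(
            time=np.asarray(sidecar["force"]["t"], dtype=float),
            force=np.asarray(sidecar["force"]["F"], dtype=float),
            setpoint=sidecar["force"].get("setpoint"),
        )
    return Kymograph(
        counts={ch: stack[i] for i, ch in enumerate(channels)},
        line_time=sidecar["line_time_s"],
        pixel_size=sidecar["pixel_size_nm"],
        saturation_level=sidecar.get("saturation_level"),
        force=force,
        metadata=sidecar.get("metadata", {}),
    )


def write_kymograph_hdf5(kymo: Kymograph, path: Union[str, Path]) -> Path:
    """Write the HDF5 container dialect."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("kymo")
        for ch, arr in kymo.counts.items():
            grp.create_dataset(ch, data=arr)
        grp.create_dataset("line_time_s", data=kymo.line_time)
        grp.create_dataset("pixel_size_nm", data=kymo.pixel_size)
        if kymo.saturation_level is not None:
            grp.create_dataset("saturation_level", data=kymo.saturation_level)
        if kymo.force is not None:
            fg = f.create_group("force")
            fg.create_dataset("t", data=kymo.force.time)
            fg.create_dataset("F", data=kymo.force.force)
    return path


def _read_kymograph_hdf5(path: Path) -> Kymograph:
    with h5py.File(path, "r") as f:
        if "kymo" not in f:
            raise KeyError("HDF5 container is missing required group 'kymo'")
        grp = f["kymo"]
        for field in ("line_time_s", "pixel_size_nm"):
            if field not in grp:
                raise KeyError(f"HDF5 container is missing required field 'kymo/{field}'")
        counts = {
            ch: grp[ch][()]
            for ch in ("green", "red")
            if ch in grp and getattr(grp[ch], "ndim", 0) == 2
        }
        if not counts:
            raise KeyError("HDF5 container has no channel dataset (kymo/green or kymo/red)")
        force = None
        if "force" in f:
            force = ForceTrace(time=f["force/t"][()], force=f["force/F"][()])
        sat = grp["saturation_level"][()] if "saturation_level" in grp else None
        return Kymograph(
            counts=counts,
            line_time=float(grp["line_time_s"][()]),
            pixel_size=float(grp["pixel_size_nm"][()]),
            saturation_level=float(sat) if sat is not None else None,
            force=force,
        )


def read_kymograph(path: Union[str, Path]) -> Kymograph:
    """Read a kymograph from TIFF+sidecar or the HDF5 container."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_kymograph_tiff(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_kymograph_hdf5(path)
    raise ValueError(f"unrecognised kymograph format {path.suffix!r}")


# --- curves, trajectories, dwells ----------------------------------------


def curve_to_csv(curve: ForceExtensionCurve, path: Union[str, Path]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# pulling_rate_um_s={curve.pulling_rate}\n")
        fh.write(f"# sample_rate_hz={curve.sample_rate}\n")
        pd.DataFrame(
            {
                "time_s": curve.time,
                "extension_nm": curve.extension,
                "force_pN": curve.force,
                "direction": curve.direction,
            }
        ).to_csv(fh, index=False)
    return path


def curve_from_csv(path: Union[str, Path]) -> ForceExtensionCurve:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "extension_nm", "force_pN"):
        if col not in df:
            raise KeyError(f"curve CSV is missing required column {col!r}")
    direction = str(df["direction"].iloc[0]) if "direction" in df else "stretch"
    return ForceExtensionCurve(
        extension=df["extension_nm"].to_numpy(),
        force=df["force_pN"].to_numpy(),
        time=df["time_s"].to_numpy(),
        direction=direction,
        pulling_rate=meta.get("pulling_rate_um_s", 0.2),
        sample_rate=meta.get("sample_rate_hz", 60.0),
    )


def trajectories_to_csv(trajectories: list[Trajectory], path: Union[str, Path]) -> Path:
    rows = []
    for tid, traj in enumerate(trajectories):
        n = len(traj)
        rows.append(
            pd.DataFrame(
                {
                    "traj_id": tid,
                    "t_s": traj.time,
                    "pos_nm": traj.position_nm,
                    "pos_kbp": traj.position_kbp if traj.position_kbp is not None else np.nan,
                    "amplitude": traj.amplitude if traj.amplitude is not None else np.nan,
                    "width_px": traj.width_px if traj.width_px is not None else np.nan,
                    "gap": traj.gap.astype(int),
                    "state": traj.states if traj.states is not None else [""] * n,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["traj_id", "t_s", "pos_nm", "pos_kbp", "amplitude", "width_px", "gap", "state"]
    )
    df.to_csv(path, index=False)
    return Path(path)


def trajectories_from_csv(path: Union[str, Path]) -> list[Trajectory]:
    df = pd.read_csv(path)
    out = []
    for _, grp in df.groupby("traj_id", sort=True):
        states = None
        if "state" in grp and grp["state"].notna().any() and (grp["state"] != "").any():
            states = grp["state"].astype(str).to_numpy(dtype=object)
        out.append(
            Trajectory(
                time=grp["t_s"].to_numpy(),
                position_nm=grp["pos_nm"].to_numpy(),
                position_kbp=(
                    grp["pos_kbp"].to_numpy() if grp["pos_kbp"].notna().all() else None
                ),
                amplitude=grp["amplitude"].to_numpy(),
                width_px=grp["width_px"].to_numpy(),
                gap=grp["gap"].to_numpy().astype(bool) if "gap" in grp else None,
                states=states,
            )
        )
    return out


def dwells_to_csv(
    records: list[tuple[float, float, bool]], path: Union[str, Path]
) -> Path:
    """Write (force_pN, dwell_s, censored) rows."""
    pd.DataFrame(records, columns=["force_pN", "dwell_s", "censored"]).to_csv(
        path, index=False
    )
    return Path(path)


def dwells_from_csv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("force_pN", "dwell_s"):
        if col not in df:
            raise KeyError(f"dwell CSV is missing required column {col!r}")
    if "censored" not in df:
        df["censored"] = False
    df["censored"] = df["censored"].astype(bool)
    return df


# --- run configuration ----------------------------------------------------

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {
        "duration": 60.0,
        "line_time": 0.1,
        "pixel_size": 100.0,
        "n_pixels": 140,
        "D_true": 0.02,
        "junction_position_kbp": 7.5,
        "psf_sigma": 150.0,
        "peak_counts": 100.0,
        "background": 2.0,
        "bead_diameter_um": 4.5,
        "bleach_step_count": 0,
        "tether_length_kbp": 15.0,
        "tether_extension_nm": 4700.0,
        "clamp_setpoint_pN": 5.0,
        "cleavage_rate": 0.16,
    },
    "force": {
        "fit_low": 3.0,
        "fit_high": 18.0,
        "post_low": 23.0,
        "post_high": 29.0,
        "threshold_factor": 3.0,
        "persistence": 5,
    },
    "track": {
        "max_step_nm": 1000.0,
        "max_gap": 3,
        "min_duration_s": 1.0,
    },
    "segment": {
        "window": 51,
        "threshold_D": 0.001,
        "min_segment_s": 1.0,
    },
    "msd": {
        "lag_min": 3,
        "lag_max": 10,
        "se_threshold_um2_s": 0.001,
        "min_duration_s": 10.0,
    },
    "kinetics": {
        "threshold_pN": 1.0,
        "min_low_duration_s": 0.2,
        "bin_width_s": 2.0,
    },
}


def _merge_validate(defaults: dict, override: dict, path: str = "") -> dict:
    merged = dict(defaults)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise KeyError(f"unknown configuration key {where!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration section {where!r} must be a mapping")
            merged[key] = _merge_validate(defaults[key], value, where)
        else:
            merged[key] = value
    return merged


class RunConfig:
    """Validated, serializable pipeline configuration.

    Wraps a nested mapping of module defaults; unknown keys are rejected
    so typos cannot silently fall back to defaults. The configuration
    hash (sha256 of the canonical JSON) stamps every output for
    provenance.
    """

    def __init__(self, overrides: Optional[dict] = None):
        self._data = _merge_validate(DEFAULT_CONFIG, overrides or {})

    def __getitem__(self, key: str) -> Any:
        return self._data[key]

    @property
    def seed(self) -> int:
        return int(self._data["seed"])

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self._data))

    def to_json(self) -> str:
        return json.dumps(self._data, sort_keys=True, indent=1)

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self._data, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text)
            if path.suffix.lower() == ".json"
            else yaml.safe_load(text)
        )
        return cls(data or {})

    def save(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(self.to_json())
        else:
            path.write_text(yaml.safe_dump(self._data, sort_keys=True))
        return path
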