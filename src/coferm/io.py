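"""File I/O: trajectory CSV dialect, parameter configs, fit reports.

Concentrations are g/L, biomass g DCW/L, time h throughout; there is no
unit-conversion layer.  Trajectory files use the documented header
``time_h, biomass_gdcw_L, cellobiose_g_L, xylose_g_L, ethanol_g_L`` with
optional per-strain biomass and replicate columns; a sugar that is absent
from an experiment is written as 0.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .coculture import CocultureParams, DEFAULT_SHARE_EXPONENT
from .estimate import FitResult
from .kinetics import StrainKinetics, Trajectory

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "load_params",
    "packaged_params_path",
    "write_fit_report",
]

_REQUIRED = ["time_h", "biomass_gdcw_L", "cellobiose_g_L", "xylose_g_L",
             "ethanol_g_L"]
_OPTIONAL = ["biomass_ej2_gdcw_L", "biomass_sr8_gdcw_L", "replicate"]

_DATA_DIR = Path(__file__).parent / "data"


class TrajectoryParseError(ValueError):
    pass


def packaged_params_path(name: str) -> Path:
    """Path of a packaged parameter fixture: 'ej2', 'sr8' or 'coculture_default'."""
    path = _DATA_DIR / f"{name}.yaml"
    if not path.exists():
        available = sorted(p.stem for p in _DATA_DIR.glob("*.yaml"))
        raise FileNotFoundError(f"no packaged parameter set {name!r}; "
                                f"available: {available}")
    return path


def read_trajectory_csv(path: Union[str, Path]) -> List[Trajectory]:
    """Read trajectories from CSV; one Trajectory per replicate index.

    Raises a parse error naming the offending row for non-numeric cells or
    non-monotone time within a replicate.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    unknown = [c for c in frame.columns if c not in _REQUIRED + _OPTIONAL]
    if unknown:
        raise TrajectoryParseError(f"{path}: unknown columns {unknown}")
    numeric_cols = [c for c in frame.columns if c != "replicate"]
    for col in numeric_cols:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # 1-based + header
            raise TrajectoryParseError(
                f"{path}: non-numeric value {frame[col][bad].iloc[0]!r} "
                f"in column {col!r} at line {row}")
        if converted.isna().any():
            row = int(np.argmax(converted.isna().to_numpy())) + 2
            raise TrajectoryParseError(f"{path}: empty cell in column "
                                       f"{col!r} at line {row}")
        frame[col] = converted
    if "replicate" in frame.columns:
        frame["replicate"] = pd.to_numeric(frame["replicate"],
                                           errors="raise").astype(int)
        groups = [(int(rep), sub) for rep, sub in frame.groupby("replicate")]
    else:
        groups = [(None, frame)]
    out = []
    for rep, sub in groups:
        t = sub["time_h"].to_numpy()
        if np.any(np.diff(t) <= 0):
            idx = int(np.argmax(np.diff(t) <= 0))
            row = sub.index[idx + 1] + 2
            raise TrajectoryParseError(
                f"{path}: non-increasing time at line {row}"
                + (f" (replicate {rep})" if rep is not None else ""))
        data = sub.drop(columns=["replicate"], errors="ignore")
        out.append(Trajectory(data.reset_index(drop=True),
                              provenance="synthetic", replicate=rep))
    return out


def write_trajectory_csv(trajs: Union[Trajectory, Sequence[Trajectory]],
                         path: Union[str, Path]) -> Path:
    """Write one or more trajectories to CSV in the documented dialect."""
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    trajs = list(trajs)
    if not trajs:
        raise ValueError("nothing to write")
    frames = []
    with_replicate = len(trajs) > 1 or any(t.replicate is not None
                                           for t in trajs)
    for i, traj in enumerate(trajs, start=1):
        frame = traj.data.copy()
        if with_replicate:
            frame["replicate"] = traj.replicate if traj.replicate is not None else i
        frames.append(frame)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


_STRAIN_KEYS = {f.name for f in dataclasses.fields(StrainKinetics)}
_COCULTURE_KEYS = {"ej2", "sr8", "r1", "r2", "r3", "r4", "r5", "r6",
                   "S0_c", "S0_x", "X0_E", "X0_S", "share_exponent"}


def _strain_from_mapping(mapping: dict, source: Path) -> StrainKinetics:
    unknown = set(mapping) - _STRAIN_KEYS
    if unknown:
        raise ValueError(f"{source}: unknown strain parameter keys "
                         f"{sorted(unknown)}")
    if "name" not in mapping:
        mapping = {"name": source.stem.upper(), **mapping}
    try:
        return StrainKinetics(**mapping)
    except TypeError as exc:
        raise ValueError(f"{source}: incomplete strain parameter set "
                         f"({exc})") from exc


def load_params(path: Union[str, Path]) -> Union[StrainKinetics, CocultureParams]:
    """Load a strain or co-culture parameter set from YAML or JSON.

    Co-culture configs may embed the strain parameters or reference strain
    files by path (resolved relative to the config).  Unknown keys are
    rejected, naming the offenders.
    """
    path = Path(path)
    text = path.read_text()
    payload = (json.loads(text) if path.suffix.lower() == ".json"
               else yaml.safe_load(text))
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    if "r1" in payload or "ej2" in payload:
        unknown = set(payload) - _COCULTURE_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown co-culture keys {sorted(unknown)}")
        strains = {}
        for key in ("ej2", "sr8"):
            if key not in payload:
                raise ValueError(f"{path}: co-culture config requires {key!r}")
            entry = payload[key]
            if isinstance(entry, str):
                strains[key] = load_params(path.parent / entry)
            elif isinstance(entry, dict):
                strains[key] = _strain_from_mapping(entry, path)
            else:
                raise ValueError(f"{path}: {key!r} must be a mapping or a "
                                 "strain-file path")
        scalars = {k: float(v) for k, v in payload.items()
                   if k not in ("ej2", "sr8")}
        return CocultureParams(ej2=strains["ej2"], sr8=strains["sr8"],
                               **scalars)
    return _strain_from_mapping(payload, path)


def write_fit_report(fit: FitResult, outdir: Union[str, Path],
                     stem: str = "fit") -> dict:
    """Write a fit as CSV (per-parameter) plus a JSON diagnostics blob."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in StrainKinetics.field_names():
        value = getattr(fit.kinetics, name)
        rows.append({
            "parameter": name,
            "estimate": value if value is not None else "",
            "status": "free" if name in fit.free else "fixed",
            "bound_hit": fit.bound_hits.get(name, False),
        })
    csv_path = outdir / f"{stem}_parameters.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    diag = {
        "rss_g2_per_L2": fit.rss,
        "rmse_g_per_L": fit.rmse,
        "rmse_per_variable_g_per_L": fit.rmse_per_variable,
        "n_observations": fit.n_obs,
        "n_function_evaluations": fit.n_eval,
        "converged": fit.converged,
        "seed": fit.seed,
        "free_parameters": list(fit.free),
    }
    json_path = outdir / f"{stem}_diagnostics.json"
    json_path.write_text(json.dumps(diag, indent=2))
    return {"parameters_csv": str(csv_path), "diagnostics_json": str(json_path)}
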