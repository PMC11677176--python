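"""File formats: unit-annotated CSV tables, TIFF stacks, and truth JSON.

Column headers carry units (``time_ns``, ``x_um``, ``lag_s`` ...); loaders
refuse silently coerced units — a file with a ``time_ms`` column is an
error, not a conversion.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fcs import IntensityTrace
from .spt import Trajectory
from .synthetic import SyntheticTruth
from .tdfs import DecayCurve, InstrumentResponse

__all__ = [
    "save_decays",
    "load_decays",
    "save_spectrum",
    "load_spectrum",
    "save_trajectories",
    "load_trajectories",
    "save_trace",
    "load_trace",
    "save_truth",
    "load_truth",
    "write_tiff",
    "read_tiff",
    "validate_io",
]


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: expected columns {expected}, missing {missing} "
            f"(found {list(df.columns)}); units are not coerced"
        )


# -- TCSPC ------------------------------------------------------------------


def save_decays(out_dir, decays: list[DecayCurve], irf: InstrumentResponse) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for d in decays:
        pd.DataFrame({"time_ns": d.time_axis, "counts": d.counts}).to_csv(
            out / f"decay_{int(round(d.emission_wavelength))}nm.csv", index=False
        )
    pd.DataFrame({"time_ns": irf.time_axis, "counts": irf.counts}).to_csv(
        out / "irf.csv", index=False
    )


def load_decays(in_dir) -> tuple[list[DecayCurve], InstrumentResponse]:
    in_dir = Path(in_dir)
    decays = []
    for path in sorted(in_dir.glob("decay_*nm.csv")):
        df = pd.read_csv(path)
        _require_columns(df, ["time_ns", "counts"], path)
        lam = float(path.stem.split("_")[1].removesuffix("nm"))
        decays.append(DecayCurve(lam, df["time_ns"].to_numpy(), df["counts"].to_numpy()))
    irf_df = pd.read_csv(in_dir / "irf.csv")
    _require_columns(irf_df, ["time_ns", "counts"], in_dir / "irf.csv")
    irf = InstrumentResponse(irf_df["time_ns"].to_numpy(), irf_df["counts"].to_numpy())
    if not decays:
        raise ValueError(f"no decay_*nm.csv files in {in_dir}")
    return decays, irf


def save_spectrum(path, spectrum: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    spectrum.to_csv(path, index=False)


def load_spectrum(path, kind: str = "emission") -> pd.DataFrame:
    df = pd.read_csv(path)
    col = "wavelength_nm" if kind == "emission" else "lambda_ex_nm"
    _require_columns(df, [col, "intensity"], path)
    return df


# -- Trajectories -----------------------------------------------------------


def save_trajectories(path, trajs: list[Trajectory]) -> None:
    rows = []
    for tid, tr in enumerate(trajs):
        for x, y, f in zip(tr.x, tr.y, tr.frames):
            rows.append((tid, f, x, y, tr.t_ill, tr.t_delay))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        rows, columns=["traj_id", "frame", "x_um", "y_um", "t_ill_ms", "t_delay_ms"]
    ).to_csv(path, index=False)


def load_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    _require_columns(df, ["traj_id", "frame", "x_um", "y_um"], path)
    t_ill = float(df["t_ill_ms"].iloc[0]) if "t_ill_ms" in df else 5.0
    t_delay = float(df["t_delay_ms"].iloc[0]) if "t_delay_ms" in df else 15.0
    trajs = []
    for _, g in df.groupby("traj_id"):
        g = g.sort_values("frame")
        trajs.append(
            Trajectory(
                g["x_um"].to_numpy(), g["y_um"].to_numpy(), g["frame"].to_numpy(),
                t_ill=t_ill, t_delay=t_delay,
            )
        )
    return trajs


# -- FCS traces -------------------------------------------------------------


def save_trace(path, trace: IntensityTrace) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"dt_s": np.full(trace.counts.size, trace.dt), "counts": trace.counts}).to_csv(
        path, index=False
    )


def load_trace(path) -> IntensityTrace:
    df = pd.read_csv(path)
    _require_columns(df, ["dt_s", "counts"], path)
    return IntensityTrace(dt=float(df["dt_s"].iloc[0]), counts=df["counts"].to_numpy())


# -- Truth JSON and TIFF ----------------------------------------------------


def save_truth(path, truth: SyntheticTruth) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "dataset_id": truth.dataset_id,
        "parameters": {k: _jsonable(v) for k, v in truth.parameters.items()},
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    if isinstance(v, float) and not np.isfinite(v):
        return str(v)
    return v


def load_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        dataset_id=payload["dataset_id"],
        parameters=payload["parameters"],
        seed=payload["seed"],
    )


def write_tiff(path, array: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


# -- Bundle validation ------------------------------------------------------

_EXPECTED_HEADERS = {
    "decay": ["time_ns", "counts"],
    "irf": ["time_ns", "counts"],
    "spectrum": ["wavelength_nm", "intensity"],
    "excitation": ["lambda_ex_nm", "intensity"],
    "trajectories": ["traj_id", "frame", "x_um", "y_um"],
    "trace": ["dt_s", "counts"],
}


def _kind_of(path: Path) -> str | None:
    name = path.name
    if name.startswith("decay_"):
        return "decay"
    if name == "irf.csv":
        return "irf"
    for key in ("spectrum", "excitation", "trajectories", "trace"):
        if key in name:
            return key
    return None


def validate_io(paths) -> dict:
    """Validate a dataset bundle: CSV headers/units, TIFF readability,
    truth-file pairing.  Returns ``{"errors": [...], "checked": n}``."""
    errors = []
    checked = 0
    paths = [Path(p) for p in paths]
    names = {p.name for p in paths}
    for p in paths:
        checked += 1
        if not p.exists():
            errors.append(f"{p}: missing")
            continue
        if p.suffix == ".csv":
            kind = _kind_of(p)
            if kind is None:
                continue
            try:
                df = pd.read_csv(p, nrows=5)
                _require_columns(df, _EXPECTED_HEADERS[kind], p)
            except ValueError as exc:
                errors.append(str(exc))
        elif p.suffix in {".tif", ".tiff"}:
            try:
                tifffile.TiffFile(p).close()
            except Exception as exc:  # corrupt file
                errors.append(f"{p}: unreadable TIFF ({exc})")
            truth_name = p.stem + "_truth.json"
            if truth_name not in names and "truth" not in names:
                errors.append(f"{p}: no paired truth JSON ({truth_name})")
    return {"errors": errors, "checked": checked}
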