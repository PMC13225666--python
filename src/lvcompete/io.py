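"""Readers and writers for the plate CSV dialect and result artifacts.

Plate files are long-format UTF-8 CSV with header
``well_id,caf,drug,seeding_ratio,replicate,time_h,channel,intensity``,
``caf``/``drug`` as 0/1 flags and ``channel`` in {sensitive, resistant}.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult, StagedEstimates
from .phaseplane import EquilibriumReport
from .plates import WellRecord
from .stats import TestReport, reports_to_frame

__all__ = [
    "PLATE_COLUMNS",
    "PlateSchemaError",
    "wells_to_frame",
    "frame_to_wells",
    "write_plate_csv",
    "read_plate_csv",
    "write_fit_results_jsonl",
    "write_stage_summary_csv",
    "write_test_reports_csv",
    "write_equilibrium_json",
    "load_config",
]

PLATE_COLUMNS = [
    "well_id", "caf", "drug", "seeding_ratio", "replicate",
    "time_h", "channel", "intensity",
]

CHANNELS = ("sensitive", "resistant")


class PlateSchemaError(ValueError):
    """The file does not conform to the plate CSV dialect."""


def wells_to_frame(wells: Sequence[WellRecord]) -> pd.DataFrame:
    rows = []
    for w in wells:
        for ch in CHANNELS:
            v = w.channel(ch)
            for t, x in zip(w.times, v):
                rows.append((w.well_id, int(w.caf), int(w.drug), w.seeding_ratio,
                             w.replicate, float(t), ch, float(x)))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def frame_to_wells(df: pd.DataFrame) -> list[WellRecord]:
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateSchemaError(f"missing required columns: {missing}")
    bad_channel = ~df["channel"].isin(CHANNELS)
    if bad_channel.any():
        row = int(np.flatnonzero(bad_channel.to_numpy())[0])
        raise PlateSchemaError(f"row {row}: unknown channel {df['channel'].iloc[row]!r}")
    dup = df.duplicated(subset=["well_id", "time_h", "channel"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise PlateSchemaError(
            f"row {row}: duplicate (well_id, time_h, channel) entry "
            f"{tuple(df.loc[df.index[row], ['well_id', 'time_h', 'channel']])}"
        )

    wells = []
    for well_id, g in df.groupby("well_id", sort=False):
        piv = g.pivot(index="time_h", columns="channel", values="intensity").sort_index()
        if piv.isna().any().any():
            raise PlateSchemaError(f"well {well_id}: channels sampled on unequal grids")
        times = piv.index.to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise PlateSchemaError(f"well {well_id}: non-monotone time stamps")
        meta = g.iloc[0]
        try:
            wells.append(
                WellRecord(
                    well_id=str(well_id),
                    caf=bool(int(meta["caf"])),
                    drug=bool(int(meta["drug"])),
                    seeding_ratio=float(meta["seeding_ratio"]),
                    replicate=int(meta["replicate"]),
                    times=times,
                    sensitive=piv["sensitive"].to_numpy(dtype=float),
                    resistant=piv["resistant"].to_numpy(dtype=float),
                )
            )
        except ValueError as exc:
            raise PlateSchemaError(f"well {well_id}: {exc}") from exc
    return wells


def write_plate_csv(wells: Sequence[WellRecord], path: str | Path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


def trajectory_to_frame(traj, well_id: str, caf: bool = False, drug: bool = False,
                        seeding_ratio: float = 0.5, replicate: int = 0) -> pd.DataFrame:
    """Export a model trajectory in the plate CSV dialect (both channels)."""
    rows = []
    for ch, series in (("sensitive", traj.S), ("resistant", traj.R)):
        for t, x in zip(traj.times, series):
            rows.append((well_id, int(caf), int(drug), seeding_ratio, replicate,
                         float(t), ch, float(x)))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def read_plate_csv(path: str | Path) -> list[WellRecord]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise PlateSchemaError(f"cannot parse {path}: {exc}") from exc
    return frame_to_wells(df)


def write_fit_results_jsonl(results: Iterable[FitResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in results:
            fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")


def write_stage_summary_csv(est: StagedEstimates, path: str | Path) -> None:
    """Stage summary rows: ``model,variant,environment,param,median,q25,q75,n_wells``."""
    rows = []

    def collect(results: list[FitResult], env: str, names: Iterable[str]) -> None:
        by_param: dict[str, list[float]] = {}
        for r in results:
            if not r.converged:
                continue
            d = r.params.as_dict()
            for n in names:
                by_param.setdefault(n, []).append(d[n])
        for n, vals in by_param.items():
            arr = np.asarray(vals)
            rows.append(
                {
                    "model": "logistic:ratio_dependent",
                    "variant": "staged",
                    "environment": env,
                    "param": n,
                    "median": float(np.median(arr)),
                    "q25": float(np.quantile(arr, 0.25)),
                    "q75": float(np.quantile(arr, 0.75)),
                    "n_wells": len(arr),
                }
            )

    collect([r for r in est.stage1_results if r.spec.population == "sensitive"],
            "monoculture", ["rho1", "K1"])
    collect([r for r in est.stage1_results if r.spec.population == "resistant"],
            "monoculture", ["rho2", "K2"])
    collect(est.stage2_results, "drug_monoculture", ["lam"])
    for env, g in est.alpha_table.groupby("environment", sort=False):
        for n in ("alpha_sr", "alpha_rs"):
            arr = g.loc[g["converged"], n].to_numpy()
            if len(arr) == 0:
                continue
            rows.append(
                {
                    "model": "logistic:ratio_dependent",
                    "variant": "staged",
                    "environment": env,
                    "param": n,
                    "median": float(np.median(arr)),
                    "q25": float(np.quantile(arr, 0.25)),
                    "q75": float(np.quantile(arr, 0.75)),
                    "n_wells": len(arr),
                }
            )
    pd.DataFrame(
        rows,
        columns=["model", "variant", "environment", "param", "median", "q25", "q75", "n_wells"],
    ).to_csv(path, index=False)


def write_test_reports_csv(reports: Iterable[TestReport], path: str | Path) -> None:
    reports_to_frame(reports).to_csv(path, index=False)


def write_equilibrium_json(report: EquilibriumReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML configuration mapping (by file extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    except Exception as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return cfg
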