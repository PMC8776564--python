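"""Reading, writing and validating session/cohort data.

Sessions travel as a tidy CSV (one row per trial) plus a JSON sidecar of
per-participant covariates (group, age, VVIQ items, ACE, regional volumes,
TIV) and the screen geometry.  A YAML column map adapts externally deposited
tables with different column names to the same validated schema.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .synthio import (
    DELAYS_S,
    SET_SIZES,
    MixtureParams,
    ParticipantRecord,
    ScreenSpec,
    TrialResponse,
    TrialSpec,
)

__all__ = [
    "SCHEMA_VERSION",
    "TRIAL_COLUMNS",
    "SchemaError",
    "read_sessions",
    "write_sessions",
    "load_column_map",
]

SCHEMA_VERSION = "1"

#: canonical trial-table columns, in their serialised order
TRIAL_COLUMNS = [
    "participant_id", "trial_id", "set_size", "delay_s",
    "target_id", "foil_id", "target_x", "target_y",
    "nontarget1_x", "nontarget1_y", "nontarget2_x", "nontarget2_y",
    "chosen_id", "identification_correct", "response_x", "response_y",
    "rt_s", "true_component",
]


class SchemaError(ValueError):
    """A session table violated the schema; offending rows are listed."""

    def __init__(self, message: str, rows: Optional[Sequence[int]] = None):
        self.rows = list(rows) if rows is not None else []
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


def _sidecar_path(trials_path: Union[str, Path]) -> Path:
    p = Path(trials_path)
    return p.with_name(p.stem + ".covariates.json")


def write_sessions(
    records: Sequence[ParticipantRecord],
    trials_path: Union[str, Path],
    covariates_path: Optional[Union[str, Path]] = None,
) -> tuple[Path, Path]:
    """Write a cohort to a trials CSV plus a covariates JSON sidecar.

    Column order and JSON key order are fixed, so identical inputs produce
    byte-identical files; floats use the shortest round-trip representation,
    making write-then-read lossless.
    """
    trials_path = Path(trials_path)
    covariates_path = (
        Path(covariates_path) if covariates_path else _sidecar_path(trials_path)
    )
    rows = []
    for rec in records:
        for trial, resp in rec.trials:
            nts = list(trial.nontarget_locs) + [(None, None)] * (2 - len(trial.nontarget_locs))
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "trial_id": trial.trial_id,
                    "set_size": trial.set_size,
                    "delay_s": trial.delay_s,
                    "target_id": trial.target_id,
                    "foil_id": trial.foil_id,
                    "target_x": trial.target_loc[0],
                    "target_y": trial.target_loc[1],
                    "nontarget1_x": nts[0][0],
                    "nontarget1_y": nts[0][1],
                    "nontarget2_x": nts[1][0],
                    "nontarget2_y": nts[1][1],
                    "chosen_id": resp.chosen_id,
                    "identification_correct": resp.identification_correct,
                    "response_x": resp.response_loc[0],
                    "response_y": resp.response_loc[1],
                    "rt_s": resp.rt_s,
                    "true_component": resp.true_component or "",
                }
            )
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    trials_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(trials_path, index=False)

    screen = records[0].screen if records else ScreenSpec()
    participants = {}
    for rec in records:
        entry: dict = {
            "group": rec.group,
            "age": rec.age,
            "vviq_items": list(rec.vviq_items),
        }
        if rec.ace is not None:
            entry["ace"] = rec.ace
        if rec.volumes is not None:
            entry["volumes"] = dict(sorted(rec.volumes.items()))
        if rec.tiv is not None:
            entry["tiv"] = rec.tiv
        if rec.true_mixture is not None:
            entry["true_mixture"] = {
                f: getattr(rec.true_mixture, f)
                for f in ("p_target", "p_misbind", "p_guess", "sigma_px",
                          "p_identify", "rt_mu_log", "rt_sigma_log")
            }
        participants[rec.participant_id] = entry
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "screen": {
            "width_px": screen.width_px,
            "height_px": screen.height_px,
            "margin_px": screen.margin_px,
            "min_separation_px": screen.min_separation_px,
        },
        "participants": participants,
    }
    # participants keep record order; key order is fixed by construction
    with open(covariates_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")
    return trials_path, covariates_path


def load_column_map(path: Union[str, Path]) -> dict[str, str]:
    """Load a YAML mapping of external column names to canonical ones."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError("column map must be a YAML mapping")
    return {str(k): str(v) for k, v in mapping.items()}


def _validate_trials(df: pd.DataFrame, screen: ScreenSpec) -> None:
    """Validate schema invariants, reporting offending row numbers (0-based)."""
    problems: list[tuple[str, list[int]]] = []

    bad = df.index[~df["set_size"].isin(SET_SIZES)].tolist()
    if bad:
        problems.append((f"set_size must be in {SET_SIZES}", bad))
    bad = df.index[~df["delay_s"].astype(float).isin(DELAYS_S)].tolist()
    if bad:
        problems.append((f"delay_s must be in {DELAYS_S}", bad))

    dup = df.duplicated(subset=["participant_id", "trial_id"], keep=False)
    if dup.any():
        problems.append(("duplicate trial_id within participant",
                         df.index[dup].tolist()))

    for prefix in ("target", "response"):
        x = pd.to_numeric(df[f"{prefix}_x"], errors="coerce")
        y = pd.to_numeric(df[f"{prefix}_y"], errors="coerce")
        off = ~(
            (x >= 0) & (x <= screen.width_px) & (y >= 0) & (y <= screen.height_px)
        )
        if off.any():
            problems.append((f"{prefix} location outside the declared screen",
                             df.index[off].tolist()))

    n_nt = df[["nontarget1_x", "nontarget2_x"]].notna().sum(axis=1)
    bad = df.index[n_nt != df["set_size"] - 1].tolist()
    if bad:
        problems.append(("non-target count must equal set_size - 1", bad))

    if problems:
        msg = "; ".join(
            f"{what} (rows: {rows})" for what, rows in problems
        )
        raise SchemaError(f"session table failed validation: {msg}")


def read_sessions(
    trials_path: Union[str, Path],
    covariates_path: Optional[Union[str, Path]] = None,
    schema_version: str = SCHEMA_VERSION,
    column_map: Optional[Union[Mapping[str, str], str, Path]] = None,
) -> list[ParticipantRecord]:
    """Read a cohort from a trials CSV and its covariates JSON sidecar.

    ``column_map`` (a mapping or a YAML file of ``external -> canonical``
    names) adapts externally deposited tables to the canonical schema before
    validation.  All schema invariants are checked; violations raise
    :class:`SchemaError` with the offending row numbers.
    """
    trials_path = Path(trials_path)
    if covariates_path is None:
        covariates_path = _sidecar_path(trials_path)
        if not covariates_path.exists():
            fallback = trials_path.parent / "covariates.json"
            if fallback.exists():
                covariates_path = fallback
    covariates_path = Path(covariates_path)
    if not trials_path.exists():
        raise FileNotFoundError(trials_path)
    with open(covariates_path) as fh:
        sidecar = json.load(fh)
    if str(sidecar.get("schema_version")) != str(schema_version):
        raise SchemaError(
            f"unknown schema version {sidecar.get('schema_version')!r}; "
            f"expected {schema_version!r}"
        )
    screen = ScreenSpec(**sidecar["screen"])

    df = pd.read_csv(trials_path)
    if column_map is not None:
        if not isinstance(column_map, Mapping):
            column_map = load_column_map(column_map)
        df = df.rename(columns=dict(column_map))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns and c != "true_component"]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    if "true_component" not in df.columns:
        df["true_component"] = ""
    if len(df):
        _validate_trials(df, screen)

    records: list[ParticipantRecord] = []
    participants = sidecar.get("participants", {})
    by_pid = dict(tuple(df.groupby("participant_id", sort=False))) if len(df) else {}
    for pid, entry in participants.items():
        trials: list[tuple[TrialSpec, TrialResponse]] = []
        sub = by_pid.get(pid)
        if sub is not None:
            for _, row in sub.iterrows():
                nts = []
                for k in (1, 2):
                    x, y = row[f"nontarget{k}_x"], row[f"nontarget{k}_y"]
                    if not (pd.isna(x) or pd.isna(y)):
                        nts.append((float(x), float(y)))
                trial = TrialSpec(
                    trial_id=int(row["trial_id"]),
                    set_size=int(row["set_size"]),
                    delay_s=float(row["delay_s"]),
                    target_id=int(row["target_id"]),
                    target_loc=(float(row["target_x"]), float(row["target_y"])),
                    nontarget_locs=tuple(nts),
                    foil_id=int(row["foil_id"]),
                )
                tc = row["true_component"]
                resp = TrialResponse(
                    trial_id=int(row["trial_id"]),
                    chosen_id=int(row["chosen_id"]),
                    identification_correct=bool(row["identification_correct"]),
                    response_loc=(float(row["response_x"]), float(row["response_y"])),
                    rt_s=float(row["rt_s"]),
                    true_component=None if (pd.isna(tc) or tc == "") else str(tc),
                )
                trials.append((trial, resp))
        mixture = None
        if "true_mixture" in entry:
            mixture = MixtureParams(**entry["true_mixture"])
        records.append(
            ParticipantRecord(
                participant_id=pid,
                group=entry["group"],
                age=float(entry["age"]),
                vviq_items=tuple(int(v) for v in entry["vviq_items"]),
                ace=entry.get("ace"),
                volumes=entry.get("volumes"),
                tiv=entry.get("tiv"),
                trials=trials,
                true_mixture=mixture,
                screen=screen,
            )
        )
    return records
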