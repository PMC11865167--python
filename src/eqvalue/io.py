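"""Delimited-text readers and writers for interview datasets.

Schemas (all comma-separated, UTF-8, headered):

* ``ctto.csv``: respondent_id, block, state_code, value, flagged, duration_min
* ``dce.csv``: respondent_id, block, state_a, state_b, chose_a
* ``respondents.csv``: id, ctto_block, dce_block, age_group, sex, education,
  region, duration_min

Validation enforces the 0.05 response grid on [-1, 1], well-formed state
codes, and referential integrity across the three files, reporting the
offending row number (1-based, excluding the header).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .state_space import HealthState
from .synthetic_data import RESPONSE_GRID, InterviewDataset

__all__ = ["read_interview_data", "write_interview_data", "validate_dataset"]


def _check_states(codes: pd.Series, file: str) -> None:
    for i, code in enumerate(codes):
        try:
            HealthState.from_code(code)
        except ValueError as exc:
            raise ValueError(f"{file}, row {i + 1}: {exc}") from None


def _check_grid(values: pd.Series, file: str) -> None:
    v = values.to_numpy(dtype=float)
    on_grid = (np.abs(v / RESPONSE_GRID - np.round(v / RESPONSE_GRID)) < 1e-9) & (
        (v >= -1 - 1e-9) & (v <= 1 + 1e-9)
    )
    if not on_grid.all():
        i = int(np.argmax(~on_grid))
        raise ValueError(
            f"{file}, row {i + 1}: value {v[i]} is not on the 0.05 grid within [-1, 1]"
        )


def validate_dataset(dataset: InterviewDataset) -> None:
    """Schema, grid and referential-integrity checks; raises on violation."""
    ctto, dce, resp = dataset.ctto, dataset.dce, dataset.respondents
    for col in ("respondent_id", "block", "state_code", "value"):
        if col not in ctto.columns:
            raise ValueError(f"ctto table missing column {col!r}")
    for col in ("respondent_id", "state_a", "state_b", "chose_a"):
        if col not in dce.columns:
            raise ValueError(f"dce table missing column {col!r}")
    if "id" not in resp.columns:
        raise ValueError("respondents table missing column 'id'")
    if resp["id"].duplicated().any():
        dup = resp.loc[resp["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"respondents: duplicate id {dup}")
    _check_states(ctto["state_code"], "ctto")
    _check_states(dce["state_a"], "dce")
    _check_states(dce["state_b"], "dce")
    _check_grid(ctto["value"], "ctto")
    known = set(resp["id"])
    for file, series in (("ctto", ctto["respondent_id"]), ("dce", dce["respondent_id"])):
        unknown = ~series.isin(known)
        if unknown.any():
            i = int(np.argmax(unknown.to_numpy()))
            raise ValueError(
                f"{file}, row {i + 1}: respondent {series.iloc[i]} not in respondents table"
            )


def read_interview_data(ctto_path, dce_path, respondents_path) -> InterviewDataset:
    """Read and validate the three interview tables."""
    ctto = pd.read_csv(ctto_path, dtype={"state_code": str})
    dce = pd.read_csv(dce_path, dtype={"state_a": str, "state_b": str})
    resp = pd.read_csv(respondents_path)
    if "flagged" not in ctto.columns:
        ctto["flagged"] = False
    ctto["flagged"] = ctto["flagged"].astype(bool)
    dce["chose_a"] = dce["chose_a"].astype(bool)
    dataset = InterviewDataset(ctto=ctto, dce=dce, respondents=resp)
    validate_dataset(dataset)
    return dataset


def write_interview_data(dataset: InterviewDataset, directory) -> dict[str, Path]:
    """Write ctto.csv, dce.csv and respondents.csv under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ctto": directory / "ctto.csv",
        "dce": directory / "dce.csv",
        "respondents": directory / "respondents.csv",
    }
    dataset.ctto.to_csv(paths["ctto"], index=False)
    dataset.dce.to_csv(paths["dce"], index=False)
    dataset.respondents.to_csv(paths["respondents"], index=False)
    return paths
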