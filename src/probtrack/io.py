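"""Trial-table and result readers/writers, configs and run manifests.

Trial tables are tab-separated text with one row per trial and the header
``trial  pi_t  change  category  stimulus_deg  measurement_deg  response``.
Categories are coded ``A``/``B``; the response column holds ``A``/``B``
choices (covert task) or criterion orientations in degrees (overt task).
All angles are degrees relative to the neutral criterion.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import ResponseRecord, TaskConfig, TrialSequence

__all__ = [
    "read_trials", "write_trials", "read_config", "write_config",
    "session_to_frame", "frame_to_session", "RunManifest", "write_manifest",
]

COLUMNS = ["trial", "pi_t", "change", "category", "stimulus_deg",
           "measurement_deg", "response"]


def session_to_frame(trials: TrialSequence,
                     responses: ResponseRecord) -> pd.DataFrame:
    if len(trials) != len(responses):
        raise ValueError("trial/response length mismatch")
    cat = np.where(np.asarray(trials.category) == 1, "A", "B")
    if responses.task == "covert":
        resp = np.where(np.asarray(responses.response) == 1, "A", "B")
    else:
        resp = np.asarray(responses.response, dtype=float)
    return pd.DataFrame({
        "trial": np.arange(1, len(trials) + 1),
        "pi_t": trials.pi,
        "change": trials.change.astype(int),
        "category": cat,
        "stimulus_deg": trials.stimulus,
        "measurement_deg": trials.measurement,
        "response": resp,
    })


def frame_to_session(df: pd.DataFrame, task: str | None = None,
                     config: TaskConfig | None = None
                     ) -> tuple[TrialSequence, ResponseRecord]:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    for col in ("pi_t", "stimulus_deg", "measurement_deg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"column {col!r} contains NaN or non-numeric "
                             "values")
        df = df.assign(**{col: vals})
    cats = df["category"].astype(str)
    if not cats.isin(["A", "B"]).all():
        bad = sorted(set(cats) - {"A", "B"})
        raise ValueError(f"column 'category' has values outside {{A, B}}: "
                         f"{bad}")
    resp_raw = df["response"]
    if resp_raw.isna().any():
        raise ValueError("column 'response' contains NaN")
    as_str = resp_raw.astype(str)
    looks_covert = as_str.isin(["A", "B"]).all()
    if task is None:
        task = "covert" if looks_covert else "overt"
    if task == "covert":
        if not looks_covert:
            raise ValueError("column 'response' must hold A/B choices for "
                             "the covert task")
        response = (as_str == "A").to_numpy().astype(int)
    else:
        response = pd.to_numeric(resp_raw, errors="coerce")
        if response.isna().any():
            raise ValueError("column 'response' must be numeric criterion "
                             "orientations for the overt task")
        response = response.to_numpy(dtype=float)
    trials = TrialSequence(
        pi=df["pi_t"].to_numpy(dtype=float),
        change=df["change"].to_numpy().astype(bool),
        category=(cats == "A").to_numpy().astype(int),
        stimulus=df["stimulus_deg"].to_numpy(dtype=float),
        measurement=df["measurement_deg"].to_numpy(dtype=float),
        config=config or TaskConfig(n_trials=len(df)),
    )
    return trials, ResponseRecord(task=task, response=response)


def write_trials(path, trials: TrialSequence,
                 responses: ResponseRecord) -> None:
    df = session_to_frame(trials, responses)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_trials(path, task: str | None = None,
                config: TaskConfig | None = None
                ) -> tuple[TrialSequence, ResponseRecord]:
    df = pd.read_csv(path, sep="\t")
    return frame_to_session(df, task=task, config=config)


def write_config(path, config: TaskConfig) -> None:
    data = dataclasses.asdict(config)
    data["state_set"] = list(data["state_set"])
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh)


def read_config(path) -> TaskConfig:
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    data["state_set"] = tuple(data["state_set"])
    return TaskConfig(**data)


@dataclass
class RunManifest:
    """Provenance record tying every output file to its inputs and seeds."""

    command: str
    seeds: dict
    inputs: list
    outputs: list
    config_hash: str = ""
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()
        if not self.package_version:
            from . import __version__
            self.package_version = __version__


def config_hash(config: TaskConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True,
                         default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(path, manifest: RunManifest) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
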