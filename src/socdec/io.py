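"""Dataset persistence: documented CSV/JSON schemas and validation.

A dataset directory contains, per participant ``NNN``:

* ``sub-NNN_trials.csv``  — one row per trial (amounts in integer cents)
* ``sub-NNN_ratings.csv`` — session, trial, rating (raw latent scale)
* ``sub-NNN_params.json`` — generative truth sidecar (synthetic cohorts only)

Imported real data only needs the two CSVs per participant.
"""
from __future__ import annotations

import json
import re
import warnings
from pathlib import Path

import pandas as pd

from .agents import AgentParams, ParticipantData, SyntheticDataset
from .task import CONDITIONS, TRIAL_CLASSES, TRIAL_COLUMNS

RATING_COLUMNS = ["session", "trial", "rating"]
OPTIONAL_TRIAL_COLUMNS = ["rating_probe", "participant"]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, required: list[str], path,
                   optional: list[str] = ()) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in required and c not in optional]
    if extra:
        warnings.warn(f"{path}: preserving unknown columns {extra}")


def validate_trials(df: pd.DataFrame, path="<trials>") -> None:
    _check_columns(df, TRIAL_COLUMNS, path, optional=OPTIONAL_TRIAL_COLUMNS)
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        row = int(df.index[bad_cond][0])
        raise SchemaError(f"{path}: row {row}: unknown condition "
                          f"{df.loc[row, 'condition']!r}")
    bad_class = ~df["trial_class"].isin(TRIAL_CLASSES)
    if bad_class.any():
        row = int(df.index[bad_class][0])
        raise SchemaError(f"{path}: row {row}: unknown trial_class "
                          f"{df.loc[row, 'trial_class']!r}")
    solo = df["condition"] == "solo"
    if df.loc[solo, "p_outcome"].notna().any():
        row = int(df.index[solo & df["p_outcome"].notna()][0])
        raise SchemaError(f"{path}: column p_outcome, row {row}: solo trials "
                          "cannot have a partner outcome")
    needs_p = ~solo
    if df.loc[needs_p, "p_outcome"].isna().any():
        row = int(df.index[needs_p & df["p_outcome"].isna()][0])
        raise SchemaError(f"{path}: column p_outcome, row {row}: "
                          f"{df.loc[row, 'condition']} trial lacks the "
                          "partner outcome")
    if not df["lottery_high"].gt(df["lottery_low"]).all():
        row = int(df.index[~df["lottery_high"].gt(df["lottery_low"])][0])
        raise SchemaError(f"{path}: row {row}: lottery_high must exceed "
                          "lottery_low")


def validate_ratings(df: pd.DataFrame, trials: pd.DataFrame,
                     path="<ratings>") -> None:
    _check_columns(df, RATING_COLUMNS, path)
    keys = set(zip(trials["session"], trials["trial"]))
    for i, (s, t) in enumerate(zip(df["session"], df["trial"])):
        if (s, t) not in keys:
            raise SchemaError(f"{path}: row {i}: rating at session {s} trial "
                              f"{t} has no matching trial")


def write_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for part in dataset.participants:
        stem = f"sub-{part.pid:03d}"
        part.trials.to_csv(out / f"{stem}_trials.csv", index=False)
        part.ratings.to_csv(out / f"{stem}_ratings.csv", index=False)
        if part.params is not None:
            payload = part.params.__dict__.copy()
            (out / f"{stem}_params.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True))
    return out


def read_dataset(in_dir) -> SyntheticDataset:
    src = Path(in_dir)
    trial_files = sorted(src.glob("sub-*_trials.csv"))
    if not trial_files:
        raise FileNotFoundError(f"no sub-*_trials.csv files in {src}")
    participants = []
    for tf in trial_files:
        pid = int(re.match(r"sub-(\d+)_trials\.csv", tf.name).group(1))
        trials = pd.read_csv(tf)
        validate_trials(trials, tf)
        rf = src / f"sub-{pid:03d}_ratings.csv"
        if not rf.exists():
            raise FileNotFoundError(f"{rf} missing for {tf.name}")
        ratings = pd.read_csv(rf)
        validate_ratings(ratings, trials, rf)
        pf = src / f"sub-{pid:03d}_params.json"
        params = None
        if pf.exists():
            params = AgentParams(**json.loads(pf.read_text()))
        participants.append(ParticipantData(pid=pid, params=params,
                                            trials=trials, ratings=ratings))
    return SyntheticDataset(participants=participants)
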