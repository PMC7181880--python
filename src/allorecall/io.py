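"""Session tables, run configuration, and run manifests.

Sessions are stored long: one row per target exposure (60 trials x 3
items = 180 rows), with coordinates in meters and '.' as the decimal
separator.  The long format keeps exclusion flags and the pairing-free
bias statistics simple.  Floats are written as shortest round-tripping
decimal text, so write -> read reproduces coordinates bit-exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import ResponseSet
from .observers import ObserverParams
from .task import (
    CONDITION_NAMES,
    DISPLACEMENT_FRACTIONS,
    Session,
    Trial,
    make_condition,
)

__all__ = [
    "SESSION_COLUMNS",
    "RunConfig",
    "write_session_csv",
    "read_session_csv",
    "write_manifest",
]

SESSION_COLUMNS = (
    "participant_id",
    "condition",
    "trial_index",
    "half",
    "item_index",
    "target_x",
    "target_y",
    "response_x",
    "response_y",
    "displacement_fraction",
    "excluded",
)


class SessionFormatError(ValueError):
    """A session file violates the SessionTable schema or invariants."""


@dataclass
class RunConfig:
    """Round-trippable configuration of a simulation/analysis run."""

    condition: str = "beacon_normal"
    observer: ObserverParams = field(default_factory=ObserverParams)
    n_participants: int = 12
    seed: int = 0
    alpha: float = 0.05
    halves: tuple[str, ...] = ("second",)
    exclusion_target_rule: str = "all"
    exclusion_scope: str = "left_beacon_conditions"
    bonferroni: bool = False
    output_dir: str = "out"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["halves"] = list(self.halves)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "observer" in d and isinstance(d["observer"], dict):
            d["observer"] = ObserverParams(**d["observer"])
        if "halves" in d:
            d["halves"] = tuple(d["halves"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def session_to_frame(session: Session, responses: ResponseSet | None = None) -> pd.DataFrame:
    """Flatten a session (and optional responses) to the long table."""
    if responses is not None and responses.responses.shape[0] != len(session.trials):
        raise ValueError("responses are not aligned to the session")
    rows = []
    for i, trial in enumerate(session.trials):
        for k in range(3):
            row = {
                "participant_id": session.participant_id,
                "condition": session.condition.name,
                "trial_index": trial.index,
                "half": trial.half,
                "item_index": k + 1,
                "target_x": trial.targets[k, 0],
                "target_y": trial.targets[k, 1],
                "response_x": responses.responses[i, k, 0] if responses is not None else np.nan,
                "response_y": responses.responses[i, k, 1] if responses is not None else np.nan,
                "displacement_fraction": trial.displacement_fraction,
                "excluded": bool(responses.excluded[i]) if responses is not None else False,
            }
            rows.append(row)
    return pd.DataFrame(rows, columns=list(SESSION_COLUMNS))


def write_session_csv(session: Session, responses: ResponseSet | None, path) -> None:
    """Write one session (optionally with responses) as a long CSV."""
    df = session_to_frame(session, responses)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def _fail(path, msg: str):
    raise SessionFormatError(f"{path}: {msg}")


def read_session_csv(path) -> tuple[Session, ResponseSet | None]:
    """Read and validate a session CSV written in the SessionTable schema.

    Returns (Session, ResponseSet) or (Session, None) for targets-only
    files.  Violations (missing columns, bad labels, incomplete trials,
    non-numeric coordinates) raise :class:`SessionFormatError` naming
    the offending rows.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface any parse failure uniformly
        raise SessionFormatError(f"{path}: unreadable CSV ({exc})") from exc

    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        _fail(path, f"missing columns {missing}")
    if len(df) == 0:
        _fail(path, "no data rows")
    if len(df) % 3 != 0:
        _fail(path, f"{len(df)} rows is not a whole number of 3-target trials")

    for col in ("target_x", "target_y", "displacement_fraction"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            _fail(path, f"non-numeric {col} at rows {list(bad + 2)}")
        df[col] = vals

    bad_half = df.index[~df["half"].isin(["first", "second"])]
    if len(bad_half):
        _fail(path, f"invalid half labels at rows {list(bad_half + 2)}")
    bad_item = df.index[~df["item_index"].isin([1, 2, 3])]
    if len(bad_item):
        _fail(path, f"invalid item_index at rows {list(bad_item + 2)}")
    bad_disp = df.index[
        ~df["displacement_fraction"].isin(list(DISPLACEMENT_FRACTIONS))
    ]
    if len(bad_disp):
        _fail(path, f"invalid displacement_fraction at rows {list(bad_disp + 2)}")

    pids = df["participant_id"].unique()
    conds = df["condition"].unique()
    if len(pids) != 1 or len(conds) != 1:
        _fail(path, "file must contain exactly one participant and condition")
    cond_name = str(conds[0])
    if cond_name not in CONDITION_NAMES:
        _fail(path, f"unknown condition {cond_name!r}; valid: {list(CONDITION_NAMES)}")
    condition = make_condition(cond_name)

    has_resp = df["response_x"].notna() & df["response_y"].notna()
    if has_resp.any() and not has_resp.all():
        _fail(path, "responses present for some rows but not others")
    with_responses = bool(has_resp.all())
    if with_responses:
        for col in ("response_x", "response_y"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[vals.isna()]
            if len(bad):
                _fail(path, f"non-numeric {col} at rows {list(bad + 2)}")
            df[col] = vals

    trials, resp_rows, excl = [], [], []
    for trial_index, g in df.groupby("trial_index", sort=True):
        if len(g) != 3 or sorted(g["item_index"]) != [1, 2, 3]:
            _fail(path, f"trial {trial_index} is incomplete or has duplicate items")
        g = g.sort_values("item_index")
        halves = g["half"].unique()
        disps = g["displacement_fraction"].unique()
        if len(halves) != 1 or len(disps) != 1:
            _fail(path, f"trial {trial_index} has inconsistent half/displacement")
        trials.append(
            Trial(
                index=int(trial_index),
                half=str(halves[0]),
                targets=g[["target_x", "target_y"]].to_numpy(dtype=float),
                displacement_fraction=float(disps[0]),
            )
        )
        if with_responses:
            resp_rows.append(g[["response_x", "response_y"]].to_numpy(dtype=float))
            flags = g["excluded"].astype(bool).unique()
            if len(flags) != 1:
                _fail(path, f"trial {trial_index} has inconsistent excluded flags")
            excl.append(bool(flags[0]))

    n = len(trials)
    for t in trials:
        want = "first" if t.index <= n // 2 else "second"
        if t.half != want:
            _fail(path, f"trial {t.index} labeled {t.half!r}, expected {want!r}")

    session = Session(
        participant_id=str(pids[0]), condition=condition, trials=tuple(trials), seed=None
    )
    if not with_responses:
        return session, None
    responses = ResponseSet(
        participant_id=session.participant_id,
        condition_name=cond_name,
        responses=np.stack(resp_rows),
        excluded=np.asarray(excl, dtype=bool),
    )
    return session, responses


def write_manifest(path, **entries) -> None:
    """Write a JSON run-manifest (model, params, seeds, version)."""
    from . import __version__

    payload = {"allorecall_version": __version__}
    payload.update(entries)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
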