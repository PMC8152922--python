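"""Tab-separated on-disk schemas for the pipeline's tables.

All interchange is plain TSV so that sessions, vertex scalars, fits and
screens can be inspected, diffed and produced by other tools. Columns:

* TOJ sessions: subject, condition, trial_index, soa_ms, is_catch,
  response_left_second
* vertex tables: subject, hemi, region, vertex_id, thickness_mm,
  area_mm2, mean_curv_per_mm
* subject tables: id, sex, scanner (+ optional true_reversal_value)
* fit tables: one row per subject with sigmoid/flip parameters, GoF and
  reversal summaries
* region metrics: subject, region, mct, rsi, ratio, volume, n_vertices
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic import TOJSession

SESSION_COLUMNS = [
    "subject",
    "condition",
    "trial_index",
    "soa_ms",
    "is_catch",
    "response_left_second",
]

VERTEX_COLUMNS = [
    "subject",
    "hemi",
    "region",
    "vertex_id",
    "thickness_mm",
    "area_mm2",
    "mean_curv_per_mm",
]


def write_sessions(sessions, path) -> None:
    """Write one or more TOJ sessions to a single TSV."""
    frames = []
    for s in sessions:
        df = s.trials.copy()
        df.insert(0, "condition", s.condition)
        df.insert(0, "subject", s.subject)
        frames.append(df)
    pd.concat(frames, ignore_index=True)[SESSION_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def read_sessions(path) -> list[TOJSession]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for (subject, condition), grp in df.groupby(["subject", "condition"], sort=False):
        out.append(
            TOJSession(
                subject=str(subject),
                condition=str(condition),
                trials=grp[SESSION_COLUMNS[2:]].reset_index(drop=True),
            )
        )
    return out


def write_vertex_tables(tables, path) -> None:
    """Write per-subject vertex tables (dict or iterable of DataFrames)."""
    frames = list(tables.values()) if isinstance(tables, dict) else list(tables)
    pd.concat(frames, ignore_index=True)[VERTEX_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


def read_vertex_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VERTEX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
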