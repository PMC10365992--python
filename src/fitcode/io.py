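"""Delimited-text I/O for trial tables and result records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import TRIAL_COLUMNS

__all__ = ["write_trialtable", "read_trialtable", "validate_trialtable",
           "write_result_record"]


def write_trialtable(path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trialtable(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def validate_trialtable(path) -> dict:
    """Schema and invariant checks; returns a report dict.

    Checks the fixed header, choice codes, diagonality ranges and
    contiguous trial indices per subject x context; counts rows per
    subject x context x phase. ``report["ok"]`` is False when any check
    fails, with line-numbered problems in ``report["errors"]``.
    """
    errors = []
    df = read_trialtable(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        return {"ok": False, "errors": [f"missing columns: {missing}"],
                "counts": {}}
    # +2: header line and 1-based numbering
    bad_choice = df.index[~df["choice"].isin([1, 2])]
    errors += [f"line {i + 2}: choice must be 1 or 2" for i in bad_choice]
    for col in ("d1", "d2"):
        bad = df.index[(df[col] < 0) | (df[col] > 45)]
        errors += [f"line {i + 2}: {col} outside [0, 45]" for i in bad]
    for (subj, ctx), grp in df.groupby(["subject", "context"]):
        t = grp["trial"].to_numpy()
        if not np.array_equal(np.sort(t), np.arange(1, len(t) + 1)):
            errors.append(f"subject {subj} context {ctx}: trial indices "
                          "not contiguous from 1")
    counts = (df.groupby(["subject", "context", "phase"]).size()
              .rename("rows").reset_index().to_dict("records"))
    return {"ok": not errors, "errors": errors, "counts": counts}


def write_result_record(path, record: dict) -> None:
    """JSON result record; numpy arrays become lists."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)
    Path(path).write_text(json.dumps(record, indent=2, default=default))
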