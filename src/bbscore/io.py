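"""Reading and writing the trial-table CSV and fit artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_trial_table", "write_trial_table", "write_json"]

REQUIRED_COLUMNS = ["participant_id", "trial_id", "n_tokens", "n_correct"]


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read a trial table, validating schema and count invariants.

    Required columns: participant_id, trial_id, n_tokens, n_correct.  Extra
    columns (e.g. a stimulus label) are kept.  Rows violating
    0 <= n_correct <= n_tokens or with malformed integers raise a parse
    error naming the offending row (1-based, excluding the header).
    """
    frame = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("n_tokens", "n_correct"):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = values.isna() | (values != values.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: row {row}: column {col!r} is not an integer")
        frame[col] = values.astype(int)
    invalid = (frame["n_tokens"] < 1) | (frame["n_correct"] < 0) | (
        frame["n_correct"] > frame["n_tokens"]
    )
    if invalid.any():
        row = int(np.flatnonzero(invalid.to_numpy())[0]) + 1
        raise ValueError(
            f"{path}: row {row}: violates 0 <= n_correct <= n_tokens "
            f"(n_tokens={frame['n_tokens'].iloc[row - 1]}, "
            f"n_correct={frame['n_correct'].iloc[row - 1]})"
        )
    return frame


def write_trial_table(frame: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial table missing required columns {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    def _default(value):
        if isinstance(value, (np.integer,)):
            return int(value)
        if isinstance(value, (np.floating,)):
            return float(value)
        if isinstance(value, np.ndarray):
            return value.tolist()
        raise TypeError(f"not JSON serializable: {type(value)}")

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_default) + "\n")
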