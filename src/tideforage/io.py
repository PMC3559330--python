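"""Plain-CSV readers and writers for the pipeline's standard tables.

All timestamps are written as ISO-8601 UTC and parsed back timezone-aware.
"""

from __future__ import annotations

import pandas as pd

TIME_COLS = {
    "tide": ["time"],
    "argos": ["time"],
    "tdr": ["time"],
    "glider": ["t0", "t1"],
    "wind": ["time"],
    "calendar": ["date"],
    "trips": ["time"],
    "currents": ["t_mid"],
}


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_csv(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in TIME_COLS.get(kind, []):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], utc=(kind != "calendar"))
    if kind == "argos" and "quality" in df.columns:
        df["quality"] = df["quality"].astype(str)
    return df
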