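"""Reading and writing the delimited-text interchange tables.

Comma-separated tables with a header row are the interchange format.
Parsing is strict: required columns must be present (missing ones are
named in the error), malformed rows are rejected with their line numbers,
and unknown columns are preserved.  ``read(write(x))`` round-trips.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import QUADRAT_COLUMNS, TRIAL_COLUMNS

__all__ = ["read_trials", "write_trials", "read_quadrats", "write_quadrats"]

_TRIAL_REQUIRED = ["predator_group", "prey_type", "density_offered", "consumed",
                   "dead_unconsumed", "duration_days"]
_QUADRAT_REQUIRED = ["site", "group", "count", "area_m2", "source"]


def _require(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError("%s: missing required column(s): %s" % (path, ", ".join(missing)))


def read_trials(path) -> pd.DataFrame:
    """Read a consumption-trial table, validating every row.

    Rows violating ``0 <= consumed + dead_unconsumed <= density_offered``
    or with non-positive duration are rejected with their (1-based,
    header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    _require(df, _TRIAL_REQUIRED, path)
    if "excluded" not in df.columns:
        df["excluded"] = False
    if "replicate_id" not in df.columns:
        df["replicate_id"] = [f"row-{i}" for i in range(len(df))]
    df["excluded"] = df["excluded"].astype(bool)
    for col in ("density_offered", "consumed", "dead_unconsumed"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["duration_days"] = pd.to_numeric(df["duration_days"], errors="coerce")
    bad = (
        df["density_offered"].isna()
        | df["consumed"].isna()
        | df["dead_unconsumed"].isna()
        | df["duration_days"].isna()
        | (df["density_offered"] < 0)
        | (df["consumed"] < 0)
        | (df["dead_unconsumed"] < 0)
        | (df["consumed"] + df["dead_unconsumed"] > df["density_offered"])
        | (df["duration_days"] <= 0)
    )
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad]]  # +2: header + 1-based
        raise ValueError(
            "%s: malformed trial rows at line(s) %s (counts must satisfy "
            "0 <= consumed + dead_unconsumed <= density_offered and duration > 0)"
            % (path, ", ".join(lines))
        )
    for col in ("density_offered", "consumed", "dead_unconsumed"):
        df[col] = df[col].astype(int)
    ordered = [c for c in TRIAL_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_quadrats(path) -> pd.DataFrame:
    """Read a quadrat-survey table, validating counts, areas and sources."""
    df = pd.read_csv(path)
    _require(df, _QUADRAT_REQUIRED, path)
    df["count"] = pd.to_numeric(df["count"], errors="coerce")
    df["area_m2"] = pd.to_numeric(df["area_m2"], errors="coerce")
    bad = (
        df["count"].isna()
        | df["area_m2"].isna()
        | (df["count"] < 0)
        | (df["area_m2"] <= 0)
        | ~df["source"].isin(["field", "literature"])
    )
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad]]
        raise ValueError(
            "%s: malformed quadrat rows at line(s) %s (count >= 0, area > 0, "
            "source in {field, literature})" % (path, ", ".join(lines))
        )
    df["count"] = df["count"].astype(int)
    ordered = [c for c in QUADRAT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in ordered]
    return df[ordered + extra]


def write_quadrats(quadrats: pd.DataFrame, path) -> None:
    quadrats.to_csv(path, index=False)
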