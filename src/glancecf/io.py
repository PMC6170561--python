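"""Trajectory CSV dialect.

One row per simulation step with columns ``t, v, vL, d, r, a_actuated,
sigma_a, occluded, lift`` (units: s, m/s, m/s, m, m/s, m/s^2, m/s^2,
flag, flag; '.' decimal, UTF-8, header required).  The same dialect is
used for simulated trials and external recordings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .environment import TrialRecord

__all__ = ["read_trajectory_csv", "write_trajectory_csv"]

COLUMNS = ["t", "v", "vL", "d", "r", "a_actuated", "sigma_a", "occluded",
           "lift"]
_HEADER_COMMENT = ("# glancecf trajectory: t[s] v[m/s] vL[m/s] d[m] r[m/s] "
                   "a_actuated[m/s2] sigma_a[m/s2] occluded[0/1] lift[0/1]\n")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file."""


def write_trajectory_csv(record: TrialRecord, path) -> None:
    """Write one trial to the trajectory dialect (float round-trip safe)."""
    df = pd.DataFrame({
        "t": record.t, "v": record.v, "vL": record.vL, "d": record.d,
        "r": record.r, "a_actuated": record.a, "sigma_a": record.sigma_a,
        "occluded": record.occluded.astype(int),
        "lift": record.lift.astype(int),
    })
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_HEADER_COMMENT)
        df.to_csv(fh, index=False, float_format="%.12g")


def read_trajectory_csv(path, t_G: float = 0.3) -> TrialRecord:
    """Read a trajectory CSV back into a :class:`TrialRecord`.

    ``t_G`` is the glance window of the recording protocol (not stored in
    the dialect).  Missing required columns raise a schema error naming
    the column; malformed rows raise a parse error carrying the line
    number reported by the parser.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", encoding="utf-8")
    except (pd.errors.ParserError, ValueError) as exc:
        raise TrajectoryFormatError(f"{path}: {exc}") from exc
    for col in COLUMNS:
        if col not in df.columns:
            raise TrajectoryFormatError(
                f"{path}: missing required column {col!r}")
    try:
        arr = {c: df[c].to_numpy(dtype=float) for c in COLUMNS}
    except ValueError as exc:
        raise TrajectoryFormatError(f"{path}: non-numeric data: {exc}") from exc
    if not np.all(np.isfinite(arr["t"])):
        raise TrajectoryFormatError(f"{path}: non-finite time values")
    t = arr["t"]
    dt = float(np.median(np.diff(t))) if t.size > 1 else 0.1
    occ = arr["occluded"].astype(np.int8)
    lift = arr["lift"].astype(np.int8)
    outcome = "collision" if arr["d"][-1] <= 0 else "completed"
    return TrialRecord(
        t=t, v=arr["v"], vL=arr["vL"], d=arr["d"], r=arr["r"],
        a=arr["a_actuated"], sigma_a=arr["sigma_a"], occluded=occ,
        lift=lift, outcome=outcome, seed=None, dt=dt, t_G=t_G)
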