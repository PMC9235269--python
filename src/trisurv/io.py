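"""CSV layouts and conversion between panel and record form.

Two dialects:

* **record layout** — one row per individual:
  ``subject_id, v_prev, v_last, delta_aa, delta_crc`` plus covariate
  columns.  This is the likelihood's native form.
* **panel layout** — one row per visit:
  ``subject_id, visit_time, status`` (AF, AA or CRC) plus covariate
  columns, as surveillance registries record it.  Status must be AF until
  at most one terminal AA/CRC row; any visit count reduces to one
  censoring interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .likelihood import REQUIRED_COLUMNS, validate_records

__all__ = ["read_records", "write_records", "read_panel", "write_panel",
           "panel_to_records", "records_to_panel"]

PANEL_COLUMNS = ("subject_id", "visit_time", "status")
_STATUSES = ("AF", "AA", "CRC")


def read_records(path, covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read and validate a record-layout CSV."""
    df = pd.read_csv(path)
    return validate_records(df, covariates)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing panel columns: {missing}")
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def panel_to_records(panel: pd.DataFrame) -> pd.DataFrame:
    """Reduce per-visit status rows to one censoring record per subject.

    ``v_prev`` is the last event-free visit time (0 when the event is found
    at the first visit, i.e. left-censoring); ``v_last`` the detection time,
    or the last visit for the event-free.  Status regression (AA or CRC
    followed by anything) violates the progressive model and is rejected.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"missing panel columns: {missing}")
    covs = [c for c in panel.columns if c not in PANEL_COLUMNS]
    rows, errors = [], []
    for sid, grp in panel.groupby("subject_id", sort=False):
        grp = grp.sort_values("visit_time")
        times = grp["visit_time"].to_numpy(dtype=float)
        status = grp["status"].to_numpy()
        bad = [s for s in status if s not in _STATUSES]
        if bad:
            errors.append(f"subject {sid}: unknown status {bad[0]!r}")
            continue
        if np.any(np.diff(times) <= 0) or times[0] <= 0:
            errors.append(f"subject {sid}: visit times must be positive and "
                          "strictly increasing")
            continue
        terminal = np.nonzero(status != "AF")[0]
        if terminal.size > 1 or (terminal.size == 1 and terminal[0] != len(status) - 1):
            errors.append(f"subject {sid}: terminal status must occur once, "
                          "at the final visit (no regression)")
            continue
        if terminal.size == 0:
            row = {"subject_id": sid, "v_prev": 0.0, "v_last": times[-1],
                   "delta_aa": 0, "delta_crc": 0}
        else:
            j = terminal[0]
            row = {"subject_id": sid,
                   "v_prev": 0.0 if j == 0 else times[j - 1],
                   "v_last": times[j],
                   "delta_aa": int(status[j] == "AA"),
                   "delta_crc": int(status[j] == "CRC")}
        for c in covs:
            row[c] = grp[c].iloc[0]
        rows.append(row)
    if errors:
        raise ValueError("invalid panel data:\n" + "\n".join(errors))
    return validate_records(pd.DataFrame(rows))


def records_to_panel(records: pd.DataFrame) -> pd.DataFrame:
    """Expand records to a minimal synthetic panel.

    Emits one AF row at ``v_prev`` (when positive) and a terminal row at
    ``v_last``, which preserves every censoring interval exactly;
    intermediate AF visits, being uninformative, are not reconstructed.
    """
    covs = [c for c in records.columns if c not in REQUIRED_COLUMNS]
    rows = []
    for r in records.itertuples(index=False):
        extra = {c: getattr(r, c) for c in covs}
        if r.delta_aa or r.delta_crc:
            if r.v_prev > 0:
                rows.append({"subject_id": r.subject_id, "visit_time": r.v_prev,
                             "status": "AF", **extra})
            rows.append({"subject_id": r.subject_id, "visit_time": r.v_last,
                         "status": "AA" if r.delta_aa else "CRC", **extra})
        else:
            rows.append({"subject_id": r.subject_id, "visit_time": r.v_last,
                         "status": "AF", **extra})
    return pd.DataFrame(rows)
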