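"""Plate-reader assay normalization.

Works on long-format tables with columns
``slice_id, group, timepoint, replicate, reading`` (see
:func:`mptkit.simulate.generate_assay_table` for the schema). Three
quantities are produced:

* metabolic activity as a percentage of the mean acute-timepoint reading
  (the acute mean is set at 100%), or of the matching normal-control (NC)
  group mean, in which case the % difference from NC is also reported;
* cumulative %LDH release — the running sum of per-collection LDH
  absorbances divided by the absorbance of the full-lysis (TX-100) acute
  control. Media are exchanged at every collection, so each reading is the
  release during that interval and the cumulative series is nondecreasing
  and may legitimately exceed 100%;
* replicate averaging (wells are typically run in triplicate).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["slice_id", "group", "timepoint", "reading"]

CONTROL_PREFIX = "TX100"
DEFAULT_ACUTE_LABEL = "acute"
DEFAULT_CONTROL_GROUP = "TX100_acute"
DEFAULT_NC_GROUP = "NC"


def _check_table(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assay table missing columns {missing}")
    if df.empty:
        raise ValueError("assay table is empty")
    if (df["reading"] < 0).any():
        raise ValueError("readings must be nonnegative")


def average_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells to one arithmetic-mean row per
    (slice, group, timepoint); the replicate count is kept in
    ``n_replicates``."""
    _check_table(df)
    out = (
        df.groupby(["slice_id", "group", "timepoint"], sort=False)["reading"]
        .agg(reading="mean", n_replicates="size")
        .reset_index()
    )
    return out


def normalize_metabolic(
    df: pd.DataFrame,
    basis: str = "acute_mean",
    acute_label: str = DEFAULT_ACUTE_LABEL,
    nc_group: str = DEFAULT_NC_GROUP,
) -> pd.DataFrame:
    """Express metabolic-activity readings as percentages.

    ``basis="acute_mean"``: every reading is divided by the mean
    non-control reading at the acute timepoint (set at 100%).
    ``basis="NC_mean"``: each reading is divided by the mean reading of the
    normal-control group at the *same* timepoint, and the % difference from
    NC (value − 100) is reported alongside.

    Returns columns ``slice_id, group, timepoint, value_pct, basis``
    (plus ``pct_diff_from_nc`` for the NC basis). Replicates are averaged
    first, so normalizing commutes with replicate averaging.
    """
    if basis not in ("acute_mean", "NC_mean"):
        raise ValueError(f"basis must be 'acute_mean' or 'NC_mean', got {basis!r}")
    avg = average_replicates(df)
    samples = avg[~avg["group"].str.startswith(CONTROL_PREFIX)].copy()
    controls = avg[avg["group"].str.startswith(CONTROL_PREFIX)].copy()
    if basis == "acute_mean":
        acute = samples[samples["timepoint"] == acute_label]
        if acute.empty:
            raise ValueError(f"no rows at acute timepoint {acute_label!r}")
        denom = float(acute["reading"].mean())
        if denom <= 0:
            raise ValueError("acute-mean basis is zero")
        out = pd.concat([samples, controls], ignore_index=True)
        out["value_pct"] = 100.0 * out["reading"] / denom
    else:
        nc = samples[samples["group"] == nc_group]
        if nc.empty:
            raise ValueError(f"no rows for normal-control group {nc_group!r}")
        denom_by_tp = nc.groupby("timepoint")["reading"].mean()
        out = samples[samples["group"] != nc_group].copy()
        missing = set(out["timepoint"]) - set(denom_by_tp.index)
        if missing:
            raise ValueError(f"no NC basis for timepoints {sorted(map(str, missing))}")
        denoms = out["timepoint"].map(denom_by_tp)
        if (denoms <= 0).any():
            raise ValueError("NC basis mean is zero for some timepoint")
        out["value_pct"] = 100.0 * out["reading"] / denoms
        out["pct_diff_from_nc"] = out["value_pct"] - 100.0
    out["basis"] = basis
    keep = ["slice_id", "group", "timepoint", "value_pct", "basis"]
    if basis == "NC_mean":
        keep.append("pct_diff_from_nc")
    return out[keep].reset_index(drop=True)


def cumulative_ldh_release(
    df: pd.DataFrame,
    control_group: str = DEFAULT_CONTROL_GROUP,
    timepoint_order: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Cumulative %LDH release per slice.

    %LDH(t) = 100 × (running sum of the slice's per-collection LDH
    absorbances up to t) / (mean absorbance of the TX-100 acute full-lysis
    control). The control denominator pools all ``control_group`` rows.
    TX100-flagged groups are excluded from the cumulative series (they are
    the normalizers, not samples). No ≤100% cap is applied — fully lysing
    cultures can exceed the acute control.

    ``timepoint_order`` fixes the chronological order of the timepoint
    labels; it defaults to first-appearance order in the table.
    """
    avg = average_replicates(df)
    ctrl = avg[avg["group"] == control_group]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} missing from table")
    denom = float(ctrl["reading"].mean())
    if denom <= 0:
        raise ValueError("TX-100 acute control absorbance must be positive")
    samples = avg[~avg["group"].str.startswith(CONTROL_PREFIX)].copy()
    if timepoint_order is None:
        timepoint_order = list(dict.fromkeys(samples["timepoint"]))
    order_idx = {tp: i for i, tp in enumerate(timepoint_order)}
    unknown = set(samples["timepoint"]) - set(order_idx)
    if unknown:
        raise ValueError(f"timepoints {sorted(map(str, unknown))} not in timepoint_order")
    samples["_order"] = samples["timepoint"].map(order_idx)
    samples = samples.sort_values(["slice_id", "_order"], kind="mergesort")
    samples["cumulative_absorbance"] = samples.groupby("slice_id")["reading"].cumsum()
    samples["value_pct"] = 100.0 * samples["cumulative_absorbance"] / denom
    samples["basis"] = control_group
    return samples[
        ["slice_id", "group", "timepoint", "cumulative_absorbance", "value_pct", "basis"]
    ].reset_index(drop=True)
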