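"""The event-related desynchronization/synchronization (ERD/S) statistic.

ERD% = 100 × (E − R) / R, where E is the absolute band power during the task
and R the absolute band power at rest.  Negative values are desynchronization
(cortical activation), positive values synchronization.  Powers are first
averaged into the frontal regions of interest — right Fd = (F4 + FP2)/2 and
left Fs = (F3 + FP1)/2 — and the ratio is then taken on the regional powers
(region-power-first).  The alternative order (per-channel ERD averaged within
a region) is available via ``per_channel=True`` for sensitivity analysis; the
two are different statistics and the default is asserted by a regression test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .montage import LEFT_FRONTAL, RIGHT_FRONTAL

__all__ = ["REGIONS", "region_power", "erd_percent", "erd_table"]

#: Region name → member channels.
REGIONS = {"Fd": RIGHT_FRONTAL, "Fs": LEFT_FRONTAL}


def region_power(band_power_table: pd.DataFrame) -> pd.DataFrame:
    """Average channel powers into the frontal regions Fd and Fs.

    Input: tidy frame (subject_id, condition, channel, band, absolute_power).
    Output: tidy frame (subject_id, condition, band, region, power).
    """
    required = {"subject_id", "condition", "channel", "band", "absolute_power"}
    missing = required - set(band_power_table.columns)
    if missing:
        raise ValueError(f"band power table missing column(s): {', '.join(sorted(missing))}")
    frames = []
    for region, channels in REGIONS.items():
        sub = band_power_table[band_power_table["channel"].isin(channels)]
        counts = sub.groupby(["subject_id", "condition", "band"], sort=False)["channel"].nunique()
        short = counts[counts < len(channels)]
        if not short.empty:
            key = short.index[0]
            raise ValueError(
                f"region {region}: missing channel row(s) for subject_id={key[0]}, "
                f"condition={key[1]}, band={key[2]}"
            )
        agg = (
            sub.groupby(["subject_id", "condition", "band"], as_index=False)["absolute_power"]
            .mean()
            .rename(columns={"absolute_power": "power"})
        )
        agg["region"] = region
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subject_id", "condition", "band", "region"], ignore_index=True)


def erd_percent(E, R):
    """ERD% = 100 × (E − R) / R.  Scale invariant; requires a positive baseline R."""
    E = np.asarray(E, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise ValueError("undefined baseline: rest power R must be > 0")
    if np.any(E < 0):
        raise ValueError("task power E must be >= 0")
    out = 100.0 * (E - R) / R
    return float(out) if out.ndim == 0 else out


def erd_table(region_powers: pd.DataFrame, per_channel_input: pd.DataFrame | None = None,
              per_channel: bool = False) -> pd.DataFrame:
    """ERD/S per subject × band × region from rest/task regional powers.

    Returns exactly 2 bands × 2 regions = 4 rows per subject, sorted by
    (subject_id, band, region); row order of the input does not matter.
    With ``per_channel=True`` (and the channel-level table passed as
    ``per_channel_input``), ERD is computed per channel first and then averaged
    within each region — the sensitivity-analysis variant.
    """
    if per_channel:
        if per_channel_input is None:
            raise ValueError("per_channel=True requires the channel-level band power table")
        bp = per_channel_input
        wide = bp.pivot_table(
            index=["subject_id", "band", "channel"], columns="condition",
            values="absolute_power", aggfunc="first",
        )
        _check_conditions(wide)
        ch_erd = erd_percent(wide["task"].to_numpy(), wide["rest"].to_numpy())
        frame = wide.reset_index()[["subject_id", "band", "channel"]]
        frame["erd_percent"] = ch_erd
        frame["region"] = frame["channel"].map(
            {ch: reg for reg, chans in REGIONS.items() for ch in chans}
        )
        out = (
            frame.dropna(subset=["region"])
            .groupby(["subject_id", "band", "region"], as_index=False)["erd_percent"]
            .mean()
        )
    else:
        wide = region_powers.pivot_table(
            index=["subject_id", "band", "region"], columns="condition",
            values="power", aggfunc="first",
        )
        _check_conditions(wide)
        out = wide.reset_index()[["subject_id", "band", "region"]]
        out["erd_percent"] = erd_percent(wide["task"].to_numpy(), wide["rest"].to_numpy())
    return out.sort_values(["subject_id", "band", "region"], ignore_index=True)


def _check_conditions(wide: pd.DataFrame) -> None:
    for cond in ("rest", "task"):
        if cond not in wide.columns:
            raise ValueError(f"no {cond} rows present")
        if wide[cond].isna().any():
            bad = wide.index[wide[cond].isna()][0]
            raise ValueError(f"subject {bad[0]} missing condition {cond!r} for {bad[1:]}")
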