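"""Growth-competition and drug-resistance arithmetic.

In an FP+ (fluorescent-reporter) growth competition assay, transduced
(FP+) and non-transduced (FP-) cells share a culture; the relative
proliferation of the FP+ population between day 3 and a later timepoint t
is the odds ratio of the FP+ fraction::

    RP = [N(t) * FP%(t)] * [N(d3) * (100 - FP%(d3))]
         -----------------------------------------------
         [N(d3) * FP%(d3)] * [N(t) * (100 - FP%(t))]

where N is the live-cell count and FP% the percent of FP+ cells.  The live
counts cancel algebraically, so RP depends only on the FP+ odds — both the
printed form and the cancelled form are computed and must agree.

The resistance index of construct x at drug dose m compares its RP under
drug to the control construct's (sg-Luc or wild-type cDNA):
``RI = 100 * RP(x, m) / RP(con, m)``, by default on day 9.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FlowRecord",
    "relative_proliferation",
    "resistance_index",
    "rp_table",
    "resistance_table",
]

FLOW_COLUMNS = ["construct", "replicate", "day", "live_count", "fp_percent", "drug_um"]


@dataclass(frozen=True)
class FlowRecord:
    """One flow-cytometry measurement of a competition culture."""

    construct: str
    day: float
    live_count: float
    fp_percent: float
    drug_um: float = 0.0
    replicate: str = "1"

    def __post_init__(self) -> None:
        if self.live_count < 0:
            raise ValueError("live_count must be non-negative")
        if not (0.0 <= self.fp_percent <= 100.0):
            raise ValueError("fp_percent outside [0, 100]")


def relative_proliferation(rec_t: FlowRecord, rec_d3: FlowRecord) -> float:
    """Relative proliferation of the FP+ population, timepoint vs day 3."""
    if rec_t.construct != rec_d3.construct or rec_t.replicate != rec_d3.replicate:
        raise ValueError("records must share construct and replicate")
    if rec_t.drug_um != rec_d3.drug_um:
        raise ValueError("records must share drug concentration")
    for rec in (rec_t, rec_d3):
        if rec.fp_percent in (0.0, 100.0):
            raise ValueError(
                f"undefined odds ratio: FP% = {rec.fp_percent} on day {rec.day}"
            )
    n_t, fp_t = rec_t.live_count, rec_t.fp_percent
    n_3, fp_3 = rec_d3.live_count, rec_d3.fp_percent
    as_printed = ((n_t * fp_t) * (n_3 * (100.0 - fp_3))) / (
        (n_3 * fp_3) * (n_t * (100.0 - fp_t))
    )
    cancelled = (fp_t / (100.0 - fp_t)) / (fp_3 / (100.0 - fp_3))
    if not np.isclose(as_printed, cancelled, rtol=1e-12, atol=0.0):
        raise AssertionError("live counts failed to cancel")  # pragma: no cover
    return as_printed


def resistance_index(rp_x: float, rp_con: float) -> float:
    """Percent resistance: construct RP over control RP, x100."""
    if rp_con <= 0:
        raise ValueError("control relative proliferation must be positive")
    return 100.0 * rp_x / rp_con


def _records(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(FLOW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flow table lacks columns {sorted(missing)}")
    return df


def rp_table(
    flow: pd.DataFrame,
    baseline_day: float = 3.0,
) -> pd.DataFrame:
    """Per-(construct, replicate, drug, day) relative proliferation.

    ``flow`` is a long table with columns ``construct, replicate, day,
    live_count, fp_percent, drug_um``; each group must contain the
    baseline-day measurement.
    """
    flow = _records(flow)
    rows = []
    for (construct, rep, drug), grp in flow.groupby(
        ["construct", "replicate", "drug_um"]
    ):
        base = grp[grp["day"] == baseline_day]
        if len(base) != 1:
            raise ValueError(
                f"{construct}/{rep}/{drug}: need exactly one day-{baseline_day:g} row"
            )
        rec_3 = FlowRecord(
            construct=str(construct),
            day=baseline_day,
            live_count=float(base["live_count"].iloc[0]),
            fp_percent=float(base["fp_percent"].iloc[0]),
            drug_um=float(drug),
            replicate=str(rep),
        )
        for _, row in grp.iterrows():
            if row["day"] == baseline_day:
                continue
            rec_t = FlowRecord(
                construct=str(construct),
                day=float(row["day"]),
                live_count=float(row["live_count"]),
                fp_percent=float(row["fp_percent"]),
                drug_um=float(drug),
                replicate=str(rep),
            )
            rows.append(
                {
                    "construct": construct,
                    "replicate": rep,
                    "drug_um": drug,
                    "day": row["day"],
                    "rp": relative_proliferation(rec_t, rec_3),
                }
            )
    return pd.DataFrame(rows)


def resistance_table(
    rp: pd.DataFrame,
    control: str,
    day: float = 9.0,
) -> pd.DataFrame:
    """Construct x dose resistance-index matrix (percent).

    Replicates are summarized by mean RP before the ratio is taken; the
    control construct's row is exactly 100 at every dose.
    """
    sub = rp[rp["day"] == day]
    if sub.empty:
        raise ValueError(f"no day-{day:g} relative proliferation rows")
    mean_rp = (
        sub.groupby(["construct", "drug_um"])["rp"].mean().unstack("drug_um")
    )
    if control not in mean_rp.index:
        raise ValueError(f"control construct {control!r} absent on day {day:g}")
    con = mean_rp.loc[control]
    if (con <= 0).any():
        raise ValueError("control relative proliferation must be positive")
    return 100.0 * mean_rp.div(con, axis=1)
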