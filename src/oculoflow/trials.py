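"""Trial-level filtering, condition assembly and performance summaries.

Eye analyses use correct, non-catch multiplication trials whose RT lies
within the participant's mean +/- 3 SD (RT statistics pooled over both
blocks), plus valid passive-viewing trials pooled across blocks.
Participants who answered passive-viewing trials with a solution are
excluded wholesale. Performance percentages (correct / incorrect / forgot)
are computed per block over all multiplication trials including catch
trials.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MULT_CONDITIONS = ("mult_no_distractor", "mult_distractor")


def filter_trials(trials: pd.DataFrame, rt_sd_multiplier: float = 3.0,
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trial inclusion rules; returns (included, exclusion report).

    The report has one row per excluded trial with a reason code
    (``violator`` / ``forgot`` / ``incorrect`` / ``catch`` / ``rt_outlier``
    / ``passive_invalid``); every input trial appears exactly once in
    either the included set or the report. The RT rule uses the
    participant's mean and SD over correct non-catch multiplication trials
    pooled across blocks; with fewer than 2 such trials the rule is
    skipped for that participant.
    """
    trials = trials.copy()
    reasons = pd.Series("", index=trials.index, dtype=object)

    violators = set(
        trials.loc[trials.get("passive_answered_number", False) == True,  # noqa: E712
                   "participant"].unique())
    for pid in violators:
        logger.warning("participant %s answered passive trials with a "
                       "solution; excluded wholesale", pid)
    is_violator = trials["participant"].isin(violators)
    reasons[is_violator] = "violator"

    is_mult = trials["condition"].isin(MULT_CONDITIONS)
    is_passive = trials["condition"] == "passive_viewing"

    sel = ~is_violator & is_mult
    reasons[sel & (trials["correctness"] == "forgot")] = "forgot"
    reasons[sel & (trials["correctness"] == "incorrect")] = "incorrect"
    reasons[sel & (trials["correctness"] == "correct")
            & trials["catch_flag"].astype(bool)] = "catch"

    # RT rule on the remaining correct non-catch multiplication trials.
    candidate = sel & (reasons == "")
    for pid, idx in trials[candidate].groupby("participant").groups.items():
        rts = trials.loc[idx, "response_time_ms"].to_numpy(float)
        if rts.size < 2:
            logger.warning("participant %s has < 2 correct trials; RT-SD "
                           "rule skipped", pid)
            continue
        mu, sd = float(np.mean(rts)), float(np.std(rts, ddof=1))
        if sd > 0:
            out = np.abs(rts - mu) > rt_sd_multiplier * sd
            reasons[np.asarray(idx)[out]] = "rt_outlier"

    reasons[~is_violator & is_passive
            & ~trials["passive_response_valid"].astype(bool)] = "passive_invalid"

    included = trials[reasons == ""].copy()
    report = trials.loc[reasons != "", ["participant", "trial"]].copy()
    report["reason"] = reasons[reasons != ""]
    return included, report.reset_index(drop=True)


def assemble_conditions(included: pd.DataFrame, binned: pd.DataFrame,
                        ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant condition-cell means of the corrected parameters.

    Passive-viewing trials are pooled across blocks into one cell;
    multiplication trials keep their block identity (condition already
    encodes it). Returns (cell means: participant x condition x bin x
    parameter with trial counts, flags: participants with an empty cell,
    to be removed listwise by the stats layer).
    """
    keep = set(map(tuple, included[["participant", "trial"]].to_numpy()))
    sel = binned[[tuple(x) in keep for x in
                  binned[["participant", "trial"]].to_numpy()]]
    cells = (sel.groupby(["participant", "condition", "bin", "parameter"],
                         as_index=False)
             .agg(corrected=("corrected", "mean"), raw=("raw", "mean"),
                  n_trials=("trial", "nunique")))
    conditions = ["mult_no_distractor", "mult_distractor", "passive_viewing"]
    flags = []
    for pid, grp in cells.groupby("participant"):
        missing = set(conditions) - set(grp["condition"].unique())
        if missing:
            flags.append({"participant": pid,
                          "missing_cells": sorted(missing)})
    return cells, pd.DataFrame(flags)


def performance_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per participant x block performance on multiplication trials.

    Returns percent correct / incorrect / forgot (summing to 100 per
    block), median RT and SD of RT in seconds, over all non-catch
    multiplication trials for the RT statistics and all multiplication
    trials (catch included) for the percentages.
    """
    mult = trials[trials["condition"].isin(MULT_CONDITIONS)]
    rows = []
    for (pid, block), grp in mult.groupby(["participant", "block"]):
        n = len(grp)
        if n == 0:
            continue
        counts = grp["correctness"].value_counts()
        rts = grp.loc[~grp["catch_flag"].astype(bool),
                      "response_time_ms"].to_numpy(float) / 1000.0
        rows.append({
            "participant": pid, "block": block, "n_trials": n,
            "pct_correct": 100.0 * counts.get("correct", 0) / n,
            "pct_incorrect": 100.0 * counts.get("incorrect", 0) / n,
            "pct_forgot": 100.0 * counts.get("forgot", 0) / n,
            "median_rt_s": float(np.median(rts)) if rts.size else np.nan,
            "sd_rt_s": (float(np.std(rts, ddof=1)) if rts.size > 1
                        else np.nan),
        })
    return pd.DataFrame(rows)
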