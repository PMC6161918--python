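"""The six eye parameters in 500 ms bins, with trial-wise baseline correction.

Parameters per trial and bin:

* blink, saccade and microsaccade rate (Hz): event onsets counted in the
  half-open bin [start, end) and converted to a per-second rate;
* fixation disparity (mm): median of right-minus-left horizontal gaze over
  samples not masked and not inside a blink/saccade/microsaccade;
* pupil diameter (mm): median of the binocular-mean pupil over the same
  eligible samples;
* gaze at center (%): share of bin samples (denominator includes masked
  samples) whose cyclopean gaze lies within 1 deg of the screen center;
  masked samples never count toward the numerator.

Baseline correction is subtractive and trial-wise: pupil and disparity use
the median of the 500 ms before the first operand; the three rates and
gaze-at-center use the whole 2 s multiplication-sign window (mean rate per
second / percentage over that window).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import BaselineConfig, BinningConfig
from .preprocess import binocular_pupil, fixation_disparity_mm, valid_mask

PARAMETERS = ("blink_rate", "saccade_rate", "microsaccade_rate",
              "fixation_disparity", "pupil_diameter", "gaze_at_center")

RATE_PARAMS = {"blink_rate": "blink", "saccade_rate": "saccade",
               "microsaccade_rate": "microsaccade"}


class MissingDistractorError(ValueError):
    """Raised when distractor-locked epochs are requested on a trial
    without a distractor."""


def event_rate_per_bin(onsets_ms: np.ndarray, bin_: Tuple[float, float],
                       rate_multiplier: float = 2.0) -> float:
    """Onset count in the half-open bin [start, end), times rate_multiplier.

    With 500 ms bins the multiplier 2 converts counts to Hz.
    """
    onsets_ms = np.asarray(onsets_ms, dtype=float)
    start, end = bin_
    count = int(np.sum((onsets_ms >= start) & (onsets_ms < end)))
    return count * rate_multiplier


def _median_or_nan(values: np.ndarray) -> float:
    values = values[np.isfinite(values)]
    return float(np.median(values)) if values.size else float("nan")


def gaze_at_center_pct(trial: pd.DataFrame, in_bin: np.ndarray,
                       masked: np.ndarray, center: Tuple[float, float],
                       px_per_deg: float, radius_deg: float) -> float:
    """Percent of bin samples with cyclopean gaze within radius of center.

    The denominator is every sample of the bin (blink periods included);
    masked or invalid samples cannot contribute to the numerator.
    """
    n_total = int(in_bin.sum())
    if n_total == 0:
        return float("nan")
    cx, cy = center
    gx = (trial["lx_px"].to_numpy(float) + trial["rx_px"].to_numpy(float)) / 2
    gy = (trial["ly_px"].to_numpy(float) + trial["ry_px"].to_numpy(float)) / 2
    dist_deg = np.hypot(gx - cx, gy - cy) / px_per_deg
    with np.errstate(invalid="ignore"):
        at_center = np.where(np.isfinite(dist_deg), dist_deg <= radius_deg,
                             False)
    n_in = int(np.sum(in_bin & ~masked & at_center))
    return 100.0 * n_in / n_total


def _window_values(trial: pd.DataFrame, eligible: np.ndarray,
                   masked: np.ndarray, events: pd.DataFrame,
                   blinks: pd.DataFrame, window: Tuple[float, float],
                   center: Tuple[float, float], px_per_deg: float,
                   mm_per_px: float, radius_deg: float) -> dict:
    """Raw values of the six parameters over an arbitrary time window.

    Rates are returned per second regardless of window width, so the same
    routine serves both the 500 ms analysis bins and baseline windows.
    """
    t_ms = trial["time_ms"].to_numpy(float)
    start, end = window
    in_bin = (t_ms >= start) & (t_ms < end)
    window_s = (end - start) / 1000.0
    out = {}
    for param, etype in RATE_PARAMS.items():
        table = blinks if etype == "blink" else events
        onsets = table.loc[table["type"] == etype, "onset_ms"].to_numpy(float) \
            if not table.empty else np.array([])
        count = int(np.sum((onsets >= start) & (onsets < end)))
        out[param] = count / window_s
    el = eligible & in_bin
    disp = fixation_disparity_mm(trial, mm_per_px)
    out["fixation_disparity"] = _median_or_nan(disp[el])
    out["pupil_diameter"] = _median_or_nan(binocular_pupil(trial)[el])
    out["gaze_at_center"] = gaze_at_center_pct(
        trial, in_bin, masked, center, px_per_deg, radius_deg)
    return out


def _eligible(trial: pd.DataFrame, trial_mask: pd.DataFrame,
              gaze_events: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """(eligible, masked) sample flags for pupil/disparity analysis.

    Eligible = not masked and outside every detected saccade/microsaccade
    interval (blinks are already in the mask).
    """
    masked = ~valid_mask(trial_mask)
    eligible = ~masked.copy()
    if not gaze_events.empty:
        t_ms = trial["time_ms"].to_numpy(float)
        for _, ev in gaze_events.iterrows():
            eligible &= ~((t_ms >= ev["onset_ms"]) & (t_ms <= ev["offset_ms"]))
    return eligible, masked


def extract_parameters(samples: pd.DataFrame, mask: pd.DataFrame,
                       events: pd.DataFrame, blinks: pd.DataFrame,
                       trials: pd.DataFrame,
                       binning: Optional[BinningConfig] = None,
                       baseline: Optional[BaselineConfig] = None,
                       px_per_deg: float = 45.0,
                       mm_per_px: float = 531.0 / 1920.0,
                       screen_center: Tuple[float, float] = (960.0, 540.0),
                       ) -> pd.DataFrame:
    """Per trial x bin values of the six parameters, raw and corrected.

    Returns a tidy long table: participant, trial, condition, block, bin
    (index), bin_start_ms / bin_end_ms (relative to calculation onset),
    parameter, raw, baseline, corrected. Bins with no eligible samples and
    trials with missing baselines propagate NaN.
    """
    binning = binning or BinningConfig()
    baseline = baseline or BaselineConfig()
    rows = []
    ev_by_trial = dict(tuple(events.groupby(["participant", "trial"]))) \
        if not events.empty else {}
    bl_by_trial = dict(tuple(blinks.groupby(["participant", "trial"]))) \
        if not blinks.empty else {}
    empty_ev = pd.DataFrame(columns=events.columns if not events.empty
                            else ["type", "onset_ms", "offset_ms"])
    samp_by_trial = dict(tuple(samples.groupby(["participant", "trial"]))) \
        if not samples.empty else {}
    for _, trow in trials.iterrows():
        pid, tid = trow["participant"], trow["trial"]
        tr = samp_by_trial.get((pid, tid))
        if tr is None or tr.empty:
            continue
        tr_mask = mask.loc[tr.index]
        tr_events = ev_by_trial.get((pid, tid), empty_ev)
        tr_blinks = bl_by_trial.get((pid, tid), empty_ev)
        eligible, masked = _eligible(tr, tr_mask, tr_events)
        calc = float(trow["calc_onset_ms"])
        op1 = float(trow["op1_onset_ms"])
        sign = float(trow["sign_onset_ms"])

        kwargs = dict(center=screen_center, px_per_deg=px_per_deg,
                      mm_per_px=mm_per_px,
                      radius_deg=binning.center_radius_deg)
        cont_bl = _window_values(tr, eligible, masked, tr_events, tr_blinks,
                                 (op1 - baseline.continuous_window_ms, op1),
                                 **kwargs)
        rate_bl = _window_values(tr, eligible, masked, tr_events, tr_blinks,
                                 (sign, sign + baseline.rate_window_ms),
                                 **kwargs)
        baselines = {
            "blink_rate": rate_bl["blink_rate"],
            "saccade_rate": rate_bl["saccade_rate"],
            "microsaccade_rate": rate_bl["microsaccade_rate"],
            "gaze_at_center": rate_bl["gaze_at_center"],
            "fixation_disparity": cont_bl["fixation_disparity"],
            "pupil_diameter": cont_bl["pupil_diameter"],
        }
        for b, (rel_start, rel_end) in enumerate(binning.bins):
            vals = _window_values(tr, eligible, masked, tr_events, tr_blinks,
                                  (calc + rel_start, calc + rel_end), **kwargs)
            for param in PARAMETERS:
                raw = vals[param]
                bl = baselines[param]
                rows.append({
                    "participant": pid, "trial": tid,
                    "condition": trow["condition"], "block": trow["block"],
                    "bin": b, "bin_start_ms": rel_start, "bin_end_ms": rel_end,
                    "parameter": param, "raw": raw, "baseline": bl,
                    "corrected": raw - bl,
                })
    return pd.DataFrame(rows)


def distractor_locked_epochs(samples: pd.DataFrame, mask: pd.DataFrame,
                             events: pd.DataFrame, blinks: pd.DataFrame,
                             trials: pd.DataFrame,
                             window_ms: Tuple[float, float] = (-500.0, 1000.0),
                             bin_width_ms: float = 500.0,
                             px_per_deg: float = 45.0,
                             mm_per_px: float = 531.0 / 1920.0,
                             screen_center: Tuple[float, float] = (960.0, 540.0),
                             center_radius_deg: float = 1.0) -> pd.DataFrame:
    """Six parameters in bins re-anchored to distractor onset.

    Baseline is the 500 ms immediately preceding the distractor (median for
    pupil/disparity, per-second rate and percentage for the others). Every
    trial passed in must have a distractor; otherwise
    :class:`MissingDistractorError` is raised.
    """
    lo, hi = window_ms
    n_bins = (hi - lo) / bin_width_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("window must be a whole number of bins")
    n_bins = int(round(n_bins))
    rows = []
    ev_by_trial = dict(tuple(events.groupby(["participant", "trial"]))) \
        if not events.empty else {}
    bl_by_trial = dict(tuple(blinks.groupby(["participant", "trial"]))) \
        if not blinks.empty else {}
    empty_ev = pd.DataFrame(columns=["type", "onset_ms", "offset_ms"])
    samp_by_trial = dict(tuple(samples.groupby(["participant", "trial"]))) \
        if not samples.empty else {}
    for _, trow in trials.iterrows():
        if not np.isfinite(trow["distractor_onset_ms"]):
            raise MissingDistractorError(
                f"trial {trow['trial']} of participant {trow['participant']} "
                "has no distractor")
        pid, tid = trow["participant"], trow["trial"]
        tr = samp_by_trial.get((pid, tid))
        if tr is None or tr.empty:
            continue
        tr_mask = mask.loc[tr.index]
        tr_events = ev_by_trial.get((pid, tid), empty_ev)
        tr_blinks = bl_by_trial.get((pid, tid), empty_ev)
        eligible, masked = _eligible(tr, tr_mask, tr_events)
        anchor = float(trow["distractor_onset_ms"])
        kwargs = dict(center=screen_center, px_per_deg=px_per_deg,
                      mm_per_px=mm_per_px, radius_deg=center_radius_deg)
        bl_vals = _window_values(tr, eligible, masked, tr_events, tr_blinks,
                                 (anchor - 500.0, anchor), **kwargs)
        for b in range(n_bins):
            rel_start = lo + b * bin_width_ms
            rel_end = rel_start + bin_width_ms
            vals = _window_values(tr, eligible, masked, tr_events, tr_blinks,
                                  (anchor + rel_start, anchor + rel_end),
                                  **kwargs)
            for param in PARAMETERS:
                rows.append({
                    "participant": pid, "trial": tid,
                    "condition": trow["condition"], "block": trow["block"],
                    "bin": b, "bin_start_ms": rel_start, "bin_end_ms": rel_end,
                    "parameter": param, "raw": vals[param],
                    "baseline": bl_vals[param],
                    "corrected": vals[param] - bl_vals[param],
                })
    return pd.DataFrame(rows)


def parameter_correlations(binned: pd.DataFrame,
                           value: str = "corrected") -> pd.DataFrame:
    """6x6 Pearson correlation table of the eye parameters.

    Observations are trial x bin cells of the tidy long table. Constant
    columns yield NaN entries; the diagonal is 1 where defined. Requires
    at least 3 complete observations.
    """
    wide = binned.pivot_table(index=["participant", "trial", "bin"],
                              columns="parameter", values=value)
    cols = [p for p in PARAMETERS if p in wide.columns]
    wide = wide[cols] if cols else wide
    wide = wide.dropna()
    if len(wide) < 3:
        raise ValueError("need at least 3 complete observations")
    corr = wide.corr()
    return corr
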