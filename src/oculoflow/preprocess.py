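"""Sample-level cleaning of raw binocular recordings.

Three stages, applied per trial / per participant:

1. blink detection: maximal runs of invalid pupil (either eye) of at least
   ``min_blink_run`` consecutive samples;
2. blink masking with padding: the blink span plus 2 samples (8 ms at
   250 Hz) on each side is flagged, overlapping padded spans merge;
3. extreme-value exclusion: fixed physiological ranges (pupil diameter
   > 15 mm or < 1.8 mm; |fixation disparity| > 60 mm) plus a per-
   participant mean +/- 3 SD rule, computed over samples that survived the
   blink mask, separately for pupil and disparity.

Masked samples are dropped from later analyses, never interpolated. Blink
and extreme/SD discard percentages are reported on disjoint denominators
(extreme/SD percentage is relative to non-blink samples).
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import ExclusionConfig
from .simulate import EVENT_COLUMNS

MASK_COLUMNS = ["blink", "blink_pad", "extreme_value", "sd_outlier"]


class DegenerateInputError(ValueError):
    """Raised when a computation has no valid samples to work on."""


def _runs(invalid: np.ndarray) -> List[Tuple[int, int]]:
    """Inclusive (start, stop) index pairs of maximal True runs."""
    if invalid.size == 0:
        return []
    padded = np.concatenate(([False], invalid, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def invalid_pupil(samples: pd.DataFrame) -> np.ndarray:
    """Per-sample invalidity: pupil missing or non-positive in either eye."""
    l = samples["l_pupil_mm"].to_numpy(dtype=float)
    r = samples["r_pupil_mm"].to_numpy(dtype=float)
    return ~(np.isfinite(l) & np.isfinite(r) & (l > 0) & (r > 0))


def detect_blinks(samples: pd.DataFrame, min_run: int = 3) -> pd.DataFrame:
    """Detect blinks as invalid-pupil runs of >= ``min_run`` samples.

    Operates per trial; returns an events table (EVENT_COLUMNS schema plus
    participant/trial) with type ``blink``, time-ordered, non-overlapping.
    Amplitude and peak velocity are undefined for blinks (NaN).
    """
    if samples.empty:
        return pd.DataFrame(columns=["participant", "trial"] + EVENT_COLUMNS)
    rows = []
    for (pid, tid), tr in samples.groupby(["participant", "trial"], sort=True):
        t_ms = tr["time_ms"].to_numpy()
        inv = invalid_pupil(tr)
        for i0, i1 in _runs(inv):
            if i1 - i0 + 1 >= min_run:
                rows.append((pid, tid, "blink", "both",
                             float(t_ms[i0]), float(t_ms[i1]),
                             np.nan, np.nan))
    return pd.DataFrame(rows, columns=["participant", "trial"] + EVENT_COLUMNS)


def pad_and_mask_blinks(samples: pd.DataFrame, blinks: pd.DataFrame,
                        config: ExclusionConfig) -> pd.DataFrame:
    """Flag blink samples plus ``blink_pad_samples`` on each side.

    Returns a boolean mask frame aligned with ``samples`` (columns
    ``blink`` and ``blink_pad``); padded intervals are clipped to the trial
    and merge naturally where they overlap.
    """
    mask = pd.DataFrame(False, index=samples.index,
                        columns=["blink", "blink_pad"])
    if samples.empty or blinks.empty:
        return mask
    pad = int(config.blink_pad_samples)
    blink_col = mask.columns.get_loc("blink")
    pad_col = mask.columns.get_loc("blink_pad")
    for (pid, tid), tr in samples.groupby(["participant", "trial"], sort=False):
        ev = blinks[(blinks["participant"] == pid) & (blinks["trial"] == tid)]
        if ev.empty:
            continue
        t_ms = tr["time_ms"].to_numpy()
        base = samples.index.get_indexer(tr.index)
        n = len(tr)
        for _, row in ev.iterrows():
            i0 = int(np.searchsorted(t_ms, row["onset_ms"]))
            i1 = int(np.searchsorted(t_ms, row["offset_ms"], side="right")) - 1
            mask.iloc[base[i0:i1 + 1], blink_col] = True
            p0, p1 = max(i0 - pad, 0), min(i1 + pad, n - 1)
            pre = base[p0:i0]
            post = base[i1 + 1:p1 + 1]
            if len(pre):
                mask.iloc[pre, pad_col] = True
            if len(post):
                mask.iloc[post, pad_col] = True
    # Padding never unflags: a sample may be both blink and pad of a
    # neighbouring blink; keep flags independent.
    return mask


def binocular_pupil(samples: pd.DataFrame) -> np.ndarray:
    """Mean of left and right pupil diameter (mm)."""
    return (samples["l_pupil_mm"].to_numpy(dtype=float)
            + samples["r_pupil_mm"].to_numpy(dtype=float)) / 2.0


def fixation_disparity_mm(samples: pd.DataFrame, mm_per_px: float) -> np.ndarray:
    """Right minus left horizontal gaze, converted to screen mm.

    Negative = convergent (crossed) eyes, positive = divergent.
    """
    return ((samples["rx_px"].to_numpy(dtype=float)
             - samples["lx_px"].to_numpy(dtype=float)) * mm_per_px)


def exclude_extremes(samples: pd.DataFrame, mask: pd.DataFrame,
                     config: ExclusionConfig, mm_per_px: float,
                     ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Flag physiologically implausible and per-participant outlier samples.

    Range rule: pupil diameter (either eye) > pupil_max or < pupil_min, or
    |fixation disparity| > disparity_max. SD rule: binocular pupil or
    disparity beyond the participant's mean +/- sd_multiplier * SD, with the
    statistics computed over samples not blink-masked and not range-flagged.

    Returns (full mask with ``extreme_value`` and ``sd_outlier`` columns
    added, per-participant discard summary).
    """
    out = mask.copy()
    out["extreme_value"] = False
    out["sd_outlier"] = False
    summaries = []
    blinked = (mask["blink"] | mask["blink_pad"]).to_numpy()

    l = samples["l_pupil_mm"].to_numpy(dtype=float)
    r = samples["r_pupil_mm"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        pupil_range_bad = ((l > config.pupil_max) | (l < config.pupil_min)
                           | (r > config.pupil_max) | (r < config.pupil_min))
    disp = fixation_disparity_mm(samples, mm_per_px)
    with np.errstate(invalid="ignore"):
        disp_range_bad = np.abs(disp) > config.disparity_max
    range_bad = np.where(np.isnan(l) | np.isnan(r), False,
                         pupil_range_bad) | np.where(np.isnan(disp), False,
                                                     disp_range_bad)
    out["extreme_value"] = range_bad

    pupil = binocular_pupil(samples)
    for pid, idx in samples.groupby("participant", sort=True).groups.items():
        loc = samples.index.get_indexer(idx)
        ok = ~blinked[loc] & ~range_bad[loc]
        sd_bad = np.zeros(len(loc), dtype=bool)
        for series in (pupil[loc], disp[loc]):
            vals = series[ok & np.isfinite(series)]
            if vals.size == 0:
                raise DegenerateInputError(
                    f"participant {pid}: no valid samples for SD statistics")
            if vals.size > 1:
                mu = float(np.mean(vals))
                sd = float(np.std(vals, ddof=1))
            else:
                mu, sd = float(vals[0]), 0.0
            if sd > 0:
                with np.errstate(invalid="ignore"):
                    sd_bad |= np.where(np.isfinite(series),
                                       np.abs(series - mu) > config.sd_multiplier * sd,
                                       False)
        out.iloc[loc, out.columns.get_loc("sd_outlier")] = sd_bad
        n_total = len(loc)
        n_blink = int(blinked[loc].sum())
        n_rest = n_total - n_blink
        n_extreme = int((~blinked[loc] & (range_bad[loc] | sd_bad)).sum())
        summaries.append({
            "participant": pid,
            "pct_blink_discard": 100.0 * n_blink / n_total if n_total else np.nan,
            "pct_extreme_discard": (100.0 * n_extreme / n_rest
                                    if n_rest else np.nan),
        })
    return out, pd.DataFrame(summaries)


def valid_mask(mask: pd.DataFrame) -> np.ndarray:
    """A sample is valid iff no flag is set."""
    cols = [c for c in MASK_COLUMNS if c in mask.columns]
    return ~mask[cols].any(axis=1).to_numpy()


def preprocess_samples(samples: pd.DataFrame, config: ExclusionConfig,
                       mm_per_px: float,
                       ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full cleaning pass: returns (mask, blink events, discard summary)."""
    blinks = detect_blinks(samples, config.min_blink_run)
    mask = pad_and_mask_blinks(samples, blinks, config)
    mask, summary = exclude_extremes(samples, mask, config, mm_per_px)
    return mask, blinks, summary


class SamplePreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping the cleaning pass.

    ``fit`` learns the per-participant outlier statistics implicitly by
    running the pass; ``transform`` returns the sample table with the four
    mask columns and a ``valid`` column appended. Fitted attributes:
    ``blinks_`` (blink event table) and ``discard_summary_``.
    """

    def __init__(self, config: Optional[ExclusionConfig] = None,
                 mm_per_px: float = 531.0 / 1920.0):
        self.config = config
        self.mm_per_px = mm_per_px

    def _cfg(self) -> ExclusionConfig:
        return self.config if self.config is not None else ExclusionConfig()

    def fit(self, X: pd.DataFrame, y=None) -> "SamplePreprocessor":
        mask, blinks, summary = preprocess_samples(X, self._cfg(), self.mm_per_px)
        self.mask_ = mask
        self.blinks_ = blinks
        self.discard_summary_ = summary
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "mask_") or len(self.mask_) != len(X):
            self.fit(X)
        out = X.copy()
        for col in MASK_COLUMNS:
            out[col] = self.mask_[col].to_numpy()
        out["valid"] = valid_mask(self.mask_)
        return out
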