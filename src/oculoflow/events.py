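"""Velocity-threshold saccade and microsaccade detection.

Implements the standard median-based velocity-threshold algorithm used for
microsaccade detection in fixational eye-movement research: gaze velocity
from a 5-point moving-average differentiator, a per-trial per-eye elliptic
threshold eta = lambda * sigma with sigma estimated from medians (robust to
the saccades themselves), monocular events as maximal supra-threshold runs
of a minimum duration, binocular merging by temporal overlap, and amplitude
classification (<= 1.5 deg = microsaccade).

Study settings: lambda = 6, minimum duration 2 samples (8 ms at 250 Hz),
minimum binocular overlap 1 sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .config import DetectionConfig
from .preprocess import valid_mask

BINOCULAR_EVENT_COLUMNS = ["participant", "trial", "type", "eye",
                           "onset_ms", "offset_ms", "onset_idx", "offset_idx",
                           "amplitude_deg", "peak_vel_deg_s", "binocular"]


class DegenerateThresholdError(ValueError):
    """Raised when the velocity spread is zero and no threshold exists."""


@dataclass
class MonocularEvent:
    """Supra-threshold run in one eye; sample indices are inclusive."""

    onset_idx: int
    offset_idx: int
    amplitude_deg: float
    peak_vel_deg_s: float

    @property
    def n_samples(self) -> int:
        return self.offset_idx - self.onset_idx + 1


def compute_velocity(pos: np.ndarray, dt: float) -> np.ndarray:
    """5-point moving-average differentiation of a position series (deg).

    v[n] = (x[n+2] + x[n+1] - x[n-1] - x[n-2]) / (6 dt). Exact on linear
    signals. The two samples at each edge, and any sample whose window
    touches an invalid (NaN) position, are NaN.
    """
    pos = np.asarray(pos, dtype=float)
    n = pos.size
    v = np.full(n, np.nan)
    if n < 5:
        return v
    v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) / (6.0 * dt)
    # the filter skips the center sample; an invalid sample must still have
    # invalid velocity (it is inside a masked gap)
    v[~np.isfinite(pos)] = np.nan
    return v


def velocity_threshold(vx: np.ndarray, vy: np.ndarray, lambda_: float,
                       ) -> Tuple[float, float]:
    """Elliptic detection thresholds (eta_x, eta_y) in deg/s.

    sigma is the median-based spread estimate sqrt(median(v^2) -
    median(v)^2) per component, over finite velocity samples; eta =
    lambda * sigma. Raises DegenerateThresholdError if a component has
    zero spread (e.g. constant velocity).
    """
    etas = []
    for v in (vx, vy):
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise DegenerateThresholdError("no valid velocity samples")
        var = float(np.median(v ** 2) - np.median(v) ** 2)
        if var <= 0:
            raise DegenerateThresholdError(
                "velocity spread is zero; threshold undefined")
        etas.append(lambda_ * float(np.sqrt(var)))
    return etas[0], etas[1]


def detection_criterion(vx: np.ndarray, vy: np.ndarray,
                        eta_x: float, eta_y: float) -> np.ndarray:
    """Boolean supra-threshold indicator (strict elliptic criterion)."""
    with np.errstate(invalid="ignore"):
        crit = (vx / eta_x) ** 2 + (vy / eta_y) ** 2
    return np.where(np.isfinite(crit), crit > 1.0, False)


def detect_monocular(vx: np.ndarray, vy: np.ndarray,
                     thresholds: Tuple[float, float],
                     gaze_x: np.ndarray, gaze_y: np.ndarray,
                     config: DetectionConfig) -> List[MonocularEvent]:
    """Maximal supra-threshold runs of >= min_duration_samples.

    Amplitude is the start-to-end Euclidean displacement of gaze (deg);
    peak velocity the maximum combined speed within the run.
    """
    above = detection_criterion(vx, vy, *thresholds)
    events: List[MonocularEvent] = []
    padded = np.concatenate(([False], above, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1) - 1
    for i0, i1 in zip(starts, stops):
        if i1 - i0 + 1 < config.min_duration_samples:
            continue
        dx = gaze_x[i1] - gaze_x[i0]
        dy = gaze_y[i1] - gaze_y[i0]
        speed = np.sqrt(vx[i0:i1 + 1] ** 2 + vy[i0:i1 + 1] ** 2)
        events.append(MonocularEvent(int(i0), int(i1),
                                     float(np.hypot(dx, dy)),
                                     float(np.nanmax(speed))))
    return events


def merge_binocular(left: List[MonocularEvent], right: List[MonocularEvent],
                    config: DetectionConfig) -> List[MonocularEvent]:
    """Keep binocular events: left events overlapping a right event.

    Overlap is counted in samples and must reach binocular_min_overlap.
    The merged event spans the union of the two monocular intervals; its
    amplitude and peak velocity are the means of the two eyes' values.
    Each right event is consumed by at most one left event.
    """
    merged: List[MonocularEvent] = []
    used = [False] * len(right)
    for lev in left:
        best, best_ov = None, 0
        for j, rev in enumerate(right):
            if used[j]:
                continue
            ov = (min(lev.offset_idx, rev.offset_idx)
                  - max(lev.onset_idx, rev.onset_idx) + 1)
            if ov >= config.binocular_min_overlap and ov > best_ov:
                best, best_ov = j, ov
        if best is not None:
            rev = right[best]
            used[best] = True
            merged.append(MonocularEvent(
                min(lev.onset_idx, rev.onset_idx),
                max(lev.offset_idx, rev.offset_idx),
                (lev.amplitude_deg + rev.amplitude_deg) / 2.0,
                (lev.peak_vel_deg_s + rev.peak_vel_deg_s) / 2.0))
    merged.sort(key=lambda e: e.onset_idx)
    return merged


def classify_amplitude(amplitude_deg: float, config: DetectionConfig) -> str:
    """Microsaccade iff amplitude <= micro_amplitude_max (boundary inclusive)."""
    return ("microsaccade" if amplitude_deg <= config.micro_amplitude_max
            else "saccade")


def _gaze_deg(trial: pd.DataFrame, eye: str, px_per_deg: float,
              center: Tuple[float, float]) -> Tuple[np.ndarray, np.ndarray]:
    cx, cy = center
    x = (trial[f"{eye}x_px"].to_numpy(dtype=float) - cx) / px_per_deg
    y = (trial[f"{eye}y_px"].to_numpy(dtype=float) - cy) / px_per_deg
    return x, y


def detect_saccades(samples: pd.DataFrame, mask: Optional[pd.DataFrame],
                    config: DetectionConfig, sampling_rate: float = 250.0,
                    px_per_deg: float = 45.0,
                    screen_center: Tuple[float, float] = (960.0, 540.0),
                    ) -> pd.DataFrame:
    """Detect binocular (micro)saccades on cleaned samples, per trial.

    Gaze at masked samples is treated as invalid: velocity is undefined in
    any 5-sample window touching them, so supra-threshold runs can never
    span a masked gap, and any event containing a masked sample is
    discarded. Velocity thresholds are estimated per trial and per eye
    over all valid velocity samples of that trial.

    Returns a table in BINOCULAR_EVENT_COLUMNS order (onset/offset sample
    indices are trial-local).
    """
    dt = 1.0 / sampling_rate
    rows = []
    if samples.empty:
        return pd.DataFrame(columns=BINOCULAR_EVENT_COLUMNS)
    masked_any = (~valid_mask(mask) if mask is not None
                  else np.zeros(len(samples), dtype=bool))
    for (pid, tid), tr in samples.groupby(["participant", "trial"], sort=True):
        loc = samples.index.get_indexer(tr.index)
        bad = masked_any[loc]
        t_ms = tr["time_ms"].to_numpy()
        per_eye_events = {}
        try:
            for eye in ("l", "r"):
                x, y = _gaze_deg(tr, eye, px_per_deg, screen_center)
                x = np.where(bad, np.nan, x)
                y = np.where(bad, np.nan, y)
                vx = compute_velocity(x, dt)
                vy = compute_velocity(y, dt)
                thresholds = velocity_threshold(vx, vy, config.lambda_)
                per_eye_events[eye] = detect_monocular(
                    vx, vy, thresholds, x, y, config)
        except DegenerateThresholdError:
            continue
        merged = merge_binocular(per_eye_events["l"], per_eye_events["r"],
                                 config)
        for ev in merged:
            if bad[ev.onset_idx:ev.offset_idx + 1].any():
                continue
            rows.append((pid, tid, classify_amplitude(ev.amplitude_deg, config),
                         "both", float(t_ms[ev.onset_idx]),
                         float(t_ms[ev.offset_idx]),
                         ev.onset_idx, ev.offset_idx,
                         ev.amplitude_deg, ev.peak_vel_deg_s, True))
    return pd.DataFrame(rows, columns=BINOCULAR_EVENT_COLUMNS)


class MicrosaccadeDetector(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper: sample table in, binocular event table out.

    Expects the mask columns added by :class:`SamplePreprocessor` (uses
    them when present). Parameters mirror :class:`DetectionConfig`.
    """

    def __init__(self, lambda_: float = 6.0, min_duration_samples: int = 2,
                 binocular_min_overlap: int = 1,
                 micro_amplitude_max: float = 1.5,
                 sampling_rate: float = 250.0, px_per_deg: float = 45.0,
                 screen_center: Tuple[float, float] = (960.0, 540.0)):
        self.lambda_ = lambda_
        self.min_duration_samples = min_duration_samples
        self.binocular_min_overlap = binocular_min_overlap
        self.micro_amplitude_max = micro_amplitude_max
        self.sampling_rate = sampling_rate
        self.px_per_deg = px_per_deg
        self.screen_center = screen_center

    def _config(self) -> DetectionConfig:
        return DetectionConfig(
            lambda_=self.lambda_,
            min_duration_samples=self.min_duration_samples,
            binocular_min_overlap=self.binocular_min_overlap,
            micro_amplitude_max=self.micro_amplitude_max)

    def fit(self, X: pd.DataFrame, y=None) -> "MicrosaccadeDetector":
        self.config_ = self._config()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "config_"):
            self.fit(X)
        from .preprocess import MASK_COLUMNS
        mask = X[MASK_COLUMNS] if all(c in X.columns for c in MASK_COLUMNS) \
            else None
        return detect_saccades(X, mask, self.config_, self.sampling_rate,
                               self.px_per_deg, self.screen_center)
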