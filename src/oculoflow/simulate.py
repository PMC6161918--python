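"""Synthetic binocular eye-tracking recordings with ground-truth event logs.

Emulates the multiplication-with-distractors paradigm: each trial shows a
multiplication sign for 2 s, two operands for 300 ms each, then a blank
calculation period that ends with the participant's response. In distractor
blocks a number flashes for 500 ms at one of eight positions on a 150 px
circle, 1.0-2.25 s into the calculation period (the 1.0 s onset is a catch
trial). The generator produces 250 Hz binocular gaze (pixels) and pupil
(mm) series containing fixational drift, tremor, microsaccades and saccades
on a linear main sequence, blinks (invalid-pupil runs), white vergence
noise, and a task-evoked pupil dilation during mental calculation -- plus a
ground-truth event log so detection can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

# Paradigm constants (ms): sign presentation, operand presentation each.
SIGN_MS = 2000.0
OPERAND_MS = 300.0
#: Allowed distractor onsets relative to calculation onset (ms); 1000 = catch.
DISTRACTOR_ONSETS_MS = (1000.0, 1500.0, 1750.0, 2000.0, 2250.0)
CATCH_ONSET_MS = 1000.0
DISTRACTOR_DURATION_MS = 500.0
N_DISTRACTOR_POSITIONS = 8

CONDITIONS = ("mult_no_distractor", "mult_distractor", "passive_viewing")

EVENT_COLUMNS = ["type", "eye", "onset_ms", "offset_ms",
                 "amplitude_deg", "peak_vel_deg_s"]

SAMPLE_COLUMNS = ["participant", "trial", "time_ms",
                  "lx_px", "ly_px", "rx_px", "ry_px",
                  "l_pupil_mm", "r_pupil_mm"]

TRIAL_COLUMNS = ["participant", "trial", "condition", "block",
                 "sign_onset_ms", "op1_onset_ms", "op2_onset_ms",
                 "calc_onset_ms", "distractor_onset_ms", "distractor_position",
                 "response_time_ms", "correctness", "catch_flag",
                 "passive_response_valid", "passive_answered_number"]


@dataclass
class TrialTimeline:
    """Event anchors of one trial, in ms from the start of the recording."""

    condition: str
    block: str
    sign_onset_ms: float = 0.0
    op1_onset_ms: float = SIGN_MS
    op2_onset_ms: float = SIGN_MS + OPERAND_MS
    calc_onset_ms: float = SIGN_MS + 2 * OPERAND_MS
    distractor_onset_ms: Optional[float] = None   # absolute ms, or None
    distractor_position: Optional[int] = None     # 0..7 on the 150 px circle
    response_time_ms: float = 2650.0              # from calc onset to click

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if not math.isclose(self.op1_onset_ms - self.sign_onset_ms, SIGN_MS):
            raise ConfigurationError("sign must precede op1 by 2000 ms")
        if not math.isclose(self.op2_onset_ms - self.op1_onset_ms, OPERAND_MS):
            raise ConfigurationError("op1 -> op2 gap must be 300 ms")
        if not math.isclose(self.calc_onset_ms - self.op2_onset_ms, OPERAND_MS):
            raise ConfigurationError("op2 -> calc gap must be 300 ms")
        if self.distractor_onset_ms is not None:
            rel = self.distractor_onset_ms - self.calc_onset_ms
            if not any(math.isclose(rel, v) for v in DISTRACTOR_ONSETS_MS):
                raise ConfigurationError(
                    f"distractor onset {rel} ms not in {DISTRACTOR_ONSETS_MS}")
            if self.distractor_position is None or not (
                    0 <= int(self.distractor_position) < N_DISTRACTOR_POSITIONS):
                raise ConfigurationError("distractor_position must be 0..7")
        if self.response_time_ms <= 0:
            raise ConfigurationError("response_time_ms must be positive")

    @property
    def end_ms(self) -> float:
        return self.calc_onset_ms + self.response_time_ms

    @property
    def is_catch(self) -> bool:
        return (self.distractor_onset_ms is not None and
                math.isclose(self.distractor_onset_ms - self.calc_onset_ms,
                             CATCH_ONSET_MS))


@dataclass
class GroundTruth:
    """True injected events plus the latent (noise-free) trial signals."""

    events: pd.DataFrame                 # EVENT_COLUMNS schema
    latent_gaze_deg: np.ndarray          # (n_samples, 2) cyclopean gaze
    latent_pupil_mm: np.ndarray          # (n_samples,)


def saccade_duration_s(config: SimulationConfig) -> float:
    """Duration of the raised-cosine saccade profile.

    The profile x(t) = A (1 - cos(pi t / D)) / 2 has peak velocity
    pi A / (2 D); requiring peak velocity = slope * A for every amplitude
    fixes D = pi / (2 * slope), independent of amplitude.
    """
    return math.pi / (2.0 * config.main_sequence_slope)


def _place_events(rng: np.random.Generator, n_samples: int,
                  specs: List[Tuple[str, int, float]], margin: int,
                  gap: int) -> List[Tuple[str, int, int, float]]:
    """Place events without overlap, keeping the drawn Poisson counts.

    specs: list of (kind, duration_samples, amplitude) to place. Each event
    is retried at fresh uniform onsets until it does not conflict with
    already-placed events (separated by >= `gap` samples) and lies fully
    inside [margin, n_samples - margin). Returns (kind, i0, i1, amplitude)
    with inclusive sample span [i0, i1].
    """
    placed: List[Tuple[str, int, int, float]] = []
    for kind, dur, amp in specs:
        lo, hi = margin, n_samples - margin - dur - 1
        if hi <= lo:
            continue
        for _ in range(200):
            i0 = int(rng.integers(lo, hi + 1))
            i1 = i0 + dur
            if all(i1 + gap < p0 or i0 - gap > p1 for _, p0, p1, _ in placed):
                placed.append((kind, i0, i1, amp))
                break
    placed.sort(key=lambda e: e[1])
    return placed


def simulate_trial(config: SimulationConfig, timeline: TrialTimeline,
                   rng: np.random.Generator,
                   participant: int = 0, trial: int = 0,
                   ) -> Tuple[pd.DataFrame, GroundTruth]:
    """Simulate one trial; returns (samples, ground truth).

    The sample table covers sign onset through the response (plus a short
    tail) on a uniform 250 Hz grid. Blinks render pupil and gaze invalid
    (NaN). Saccadic events obey peak_velocity = main_sequence_slope *
    amplitude exactly in the latent trajectory.
    """
    dt_ms = 1000.0 / config.sampling_rate
    n = int(round((timeline.end_ms + 100.0) / dt_ms)) + 1
    t_ms = np.arange(n) * dt_ms
    dur_s = n * config.dt

    sac_dur = max(int(round(saccade_duration_s(config) / config.dt)), 2)
    margin = 8
    gap = 5

    # Draw Poisson counts, then amplitudes / durations per event.
    specs: List[Tuple[str, int, float]] = []
    n_micro = rng.poisson(config.microsaccade_rate * dur_s)
    mu_m, sd_m = config.micro_amplitude_lognorm
    for amp in np.exp(rng.normal(mu_m, sd_m, n_micro)):
        specs.append(("microsaccade", sac_dur, float(amp)))
    calc_s = max(timeline.end_ms - timeline.calc_onset_ms, 0.0) / 1000.0
    n_sac = rng.poisson(config.saccade_rate_idc * calc_s)
    mu_s, sd_s = config.saccade_amplitude_lognorm
    sac_amps = np.exp(rng.normal(mu_s, sd_s, n_sac))
    n_blink = rng.poisson(config.blink_rate * dur_s)
    lo_b, hi_b = config.blink_duration_ms
    blink_durs = rng.uniform(lo_b, hi_b, n_blink)
    for d in blink_durs:
        specs.append(("blink", max(int(round(d / dt_ms)), 1), np.nan))

    placed = _place_events(rng, n, specs, margin, gap)

    # Saccades are restricted to the calculation period; place them there.
    calc_i0 = int(round(timeline.calc_onset_ms / dt_ms))
    if n_sac and n - margin - sac_dur - 1 > calc_i0 + margin:
        sac_specs = [("saccade", sac_dur, float(a)) for a in sac_amps]
        sac_placed: List[Tuple[str, int, int, float]] = []
        for kind, dur, amp in sac_specs:
            lo, hi = calc_i0 + 1, n - margin - dur - 1
            for _ in range(200):
                i0 = int(rng.integers(lo, hi + 1))
                i1 = i0 + dur
                others = placed + sac_placed
                if all(i1 + gap < p0 or i0 - gap > p1 for _, p0, p1, _ in others):
                    sac_placed.append((kind, i0, i1, amp))
                    break
        placed = sorted(placed + sac_placed, key=lambda e: e[1])

    # Latent cyclopean gaze: drift random walk + saccadic displacements.
    gaze = np.cumsum(rng.normal(0.0, config.drift_sd, (n, 2)), axis=0)
    records = []
    for kind, i0, i1, amp in placed:
        if kind == "blink":
            records.append(("blink", i0, i1, np.nan, np.nan))
            continue
        theta = rng.uniform(0.0, 2.0 * math.pi)
        direction = np.array([math.cos(theta), math.sin(theta)])
        span = i1 - i0
        s = np.clip((np.arange(span + 1)) / span, 0.0, 1.0)
        profile = amp * (1.0 - np.cos(math.pi * s)) / 2.0
        gaze[i0:i1 + 1] += profile[:, None] * direction[None, :]
        gaze[i1 + 1:] += amp * direction[None, :]
        peak_vel = config.main_sequence_slope * amp
        records.append((kind, i0, i1, amp, peak_vel))

    # Latent pupil: baseline + task-evoked ramp + distractor transient.
    pupil = np.full(n, config.pupil_baseline)
    if timeline.condition != "passive_viewing":
        ramp = np.clip((t_ms - timeline.calc_onset_ms) / 1000.0, 0.0, 1.0)
        pupil = pupil + config.pupil_task_gain * ramp
    if timeline.distractor_onset_ms is not None and config.pupil_distractor_gain:
        s = (t_ms - timeline.distractor_onset_ms) / 1000.0
        bump = np.where((s >= 0) & (s <= 1),
                        (1.0 - np.cos(2.0 * math.pi * np.clip(s, 0, 1))) / 2.0,
                        0.0)
        pupil = pupil + config.pupil_distractor_gain * bump

    latent_gaze = gaze.copy()
    latent_pupil = pupil.copy()

    # Emit per-eye series: vergence noise splits across eyes in x; tremor
    # is independent per eye and axis; pupil noise independent per eye.
    disp_deg = (rng.normal(0.0, config.vergence_sd, n)
                / (config.mm_per_px * config.px_per_deg))
    lx = gaze[:, 0] - disp_deg / 2 + rng.normal(0, config.tremor_sd, n)
    rx = gaze[:, 0] + disp_deg / 2 + rng.normal(0, config.tremor_sd, n)
    ly = gaze[:, 1] + rng.normal(0, config.tremor_sd, n)
    ry = gaze[:, 1] + rng.normal(0, config.tremor_sd, n)
    l_pupil = pupil + rng.normal(0, config.pupil_noise_sd, n)
    r_pupil = pupil + rng.normal(0, config.pupil_noise_sd, n)

    cx, cy = config.screen_center
    lx = cx + lx * config.px_per_deg
    rx = cx + rx * config.px_per_deg
    ly = cy + ly * config.px_per_deg
    ry = cy + ry * config.px_per_deg

    # Blinks: gaze and pupil invalid for the blink span, both eyes.
    for kind, i0, i1, _, _ in records:
        if kind == "blink":
            sl = slice(i0, i1 + 1)
            for arr in (lx, ly, rx, ry, l_pupil, r_pupil):
                arr[sl] = np.nan

    samples = pd.DataFrame({
        "participant": participant, "trial": trial,
        "time_ms": np.round(t_ms).astype(np.int64),
        "lx_px": lx, "ly_px": ly, "rx_px": rx, "ry_px": ry,
        "l_pupil_mm": l_pupil, "r_pupil_mm": r_pupil,
    })
    events = pd.DataFrame(
        [(k, "both", i0 * dt_ms, i1 * dt_ms, a, pv)
         for k, i0, i1, a, pv in records],
        columns=EVENT_COLUMNS)
    events = events.sort_values("onset_ms", kind="stable").reset_index(drop=True)
    return samples, GroundTruth(events, latent_gaze, latent_pupil)


def _assign_distractor_onsets(n_trials: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Near-balanced assignment of the five onsets across trials."""
    reps = -(-n_trials // len(DISTRACTOR_ONSETS_MS))
    pool = np.tile(DISTRACTOR_ONSETS_MS, reps)[:n_trials]
    rng.shuffle(pool)
    return pool


def _draw_rt_ms(config: SimulationConfig, rng: np.random.Generator) -> float:
    rt = math.exp(rng.normal(math.log(config.rt_median_s), config.rt_log_sd))
    return float(np.clip(rt, config.rt_min_s, 8.0)) * 1000.0


def simulate_session(config: SimulationConfig, participant: int = 0,
                     ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one participant's session.

    Two blocks (without / with distractors; order counterbalanced by
    participant parity), each with `trials_per_condition` multiplication
    trials and `passive_per_block` passive-viewing trials in random order.
    Distractor-block multiplication trials receive a distractor at one of
    the five onsets (near-balanced); onset 1.0 s marks a catch trial.
    Returns (samples, trials, ground_truth_events) tables.
    """
    meta_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, participant, 0xA11CE]))
    blocks = ["no_distractor", "distractor"]
    if participant % 2 == 1:
        blocks = blocks[::-1]

    all_samples: List[pd.DataFrame] = []
    trial_rows: List[dict] = []
    all_truth: List[pd.DataFrame] = []
    trial_idx = 0
    for block in blocks:
        kinds = (["mult"] * config.trials_per_condition
                 + ["passive"] * config.passive_per_block)
        meta_rng.shuffle(kinds)
        mult_onsets = iter(_assign_distractor_onsets(
            config.trials_per_condition, meta_rng))
        for kind in kinds:
            if kind == "mult":
                condition = ("mult_distractor" if block == "distractor"
                             else "mult_no_distractor")
                rt_ms = _draw_rt_ms(config, meta_rng)
                dist_onset = dist_pos = None
                if block == "distractor":
                    rel = float(next(mult_onsets))
                    dist_onset = SIGN_MS + 2 * OPERAND_MS + rel
                    dist_pos = int(meta_rng.integers(0, N_DISTRACTOR_POSITIONS))
                u = meta_rng.uniform()
                if u < config.accuracy:
                    correctness = "correct"
                elif meta_rng.uniform() < config.forgot_given_error:
                    correctness = "forgot"
                else:
                    correctness = "incorrect"
                passive_valid = True
                answered_number = False
            else:
                condition = "passive_viewing"
                rt_ms = float(np.clip(
                    meta_rng.normal(config.passive_duration_s, 0.4),
                    4.0, 6.5)) * 1000.0
                dist_onset = dist_pos = None
                correctness = "correct"
                passive_valid = meta_rng.uniform() >= config.passive_invalid_p
                answered_number = False
            timeline = TrialTimeline(
                condition=condition, block=block,
                distractor_onset_ms=dist_onset, distractor_position=dist_pos,
                response_time_ms=rt_ms)
            trial_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, participant, trial_idx]))
            samples, truth = simulate_trial(config, timeline, trial_rng,
                                            participant, trial_idx)
            all_samples.append(samples)
            truth_ev = truth.events.copy()
            truth_ev.insert(0, "trial", trial_idx)
            truth_ev.insert(0, "participant", participant)
            all_truth.append(truth_ev)
            trial_rows.append({
                "participant": participant, "trial": trial_idx,
                "condition": condition, "block": block,
                "sign_onset_ms": timeline.sign_onset_ms,
                "op1_onset_ms": timeline.op1_onset_ms,
                "op2_onset_ms": timeline.op2_onset_ms,
                "calc_onset_ms": timeline.calc_onset_ms,
                "distractor_onset_ms": (np.nan if dist_onset is None
                                        else dist_onset),
                "distractor_position": (np.nan if dist_pos is None
                                        else dist_pos),
                "response_time_ms": rt_ms,
                "correctness": correctness,
                "catch_flag": timeline.is_catch,
                "passive_response_valid": passive_valid,
                "passive_answered_number": answered_number,
            })
            trial_idx += 1

    if not trial_rows:
        samples = pd.DataFrame(columns=SAMPLE_COLUMNS)
        trials = pd.DataFrame(columns=TRIAL_COLUMNS)
        truth = pd.DataFrame(columns=["participant", "trial"] + EVENT_COLUMNS)
        return samples, trials, truth
    nonempty_truth = [t for t in all_truth if not t.empty]
    truth = (pd.concat(nonempty_truth, ignore_index=True) if nonempty_truth
             else pd.DataFrame(columns=["participant", "trial"]
                               + EVENT_COLUMNS))
    return (pd.concat(all_samples, ignore_index=True),
            pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS),
            truth)


def simulate_study(config: SimulationConfig,
                   ) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate all participants; concatenation of per-participant sessions."""
    parts = [simulate_session(config, p) for p in range(config.n_participants)]
    if not parts:
        return (pd.DataFrame(columns=SAMPLE_COLUMNS),
                pd.DataFrame(columns=TRIAL_COLUMNS),
                pd.DataFrame(columns=["participant", "trial"] + EVENT_COLUMNS))
    def _cat(frames, columns):
        nonempty = [f for f in frames if not f.empty]
        return (pd.concat(nonempty, ignore_index=True) if nonempty
                else pd.DataFrame(columns=columns))

    samples = _cat([p[0] for p in parts], SAMPLE_COLUMNS)
    trials = _cat([p[1] for p in parts], TRIAL_COLUMNS)
    truth = _cat([p[2] for p in parts], ["participant", "trial"] + EVENT_COLUMNS)
    return samples, trials, truth
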