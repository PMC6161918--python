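"""Binned eye parameters, baseline correction, distractor-locked epochs,
and parameter intercorrelations."""

import numpy as np
import pandas as pd
import pytest

from oculoflow.config import BinningConfig, SimulationConfig
from oculoflow.parameters import (MissingDistractorError,
                                  distractor_locked_epochs, event_rate_per_bin,
                                  extract_parameters, parameter_correlations)
from oculoflow.preprocess import MASK_COLUMNS
from tests.conftest import MM_PER_PX, make_samples

PX_PER_DEG = 45.0
CENTER = (960.0, 540.0)


def all_false_mask(samples):
    return pd.DataFrame(False, index=samples.index, columns=MASK_COLUMNS)


def trial_row(participant=0, trial=0, condition="mult_no_distractor",
              block="no_distractor", distractor_onset=np.nan, rt=3000.0):
    return pd.DataFrame([{
        "participant": participant, "trial": trial, "condition": condition,
        "block": block, "sign_onset_ms": 0.0, "op1_onset_ms": 2000.0,
        "op2_onset_ms": 2300.0, "calc_onset_ms": 2600.0,
        "distractor_onset_ms": distractor_onset, "distractor_position": np.nan,
        "response_time_ms": rt, "correctness": "correct",
        "catch_flag": False, "passive_response_valid": True,
        "passive_answered_number": False,
    }])


def event_table(rows):
    """rows: (type, onset_ms, offset_ms)"""
    return pd.DataFrame([{"participant": 0, "trial": 0, "type": t,
                          "onset_ms": on, "offset_ms": off}
                         for t, on, off in rows])


EMPTY_EVENTS = pd.DataFrame(columns=["participant", "trial", "type",
                                     "onset_ms", "offset_ms"])


def flat_trial_samples(n=1100):
    return make_samples(np.full(n, 960.0))


def run_extract(samples, events=EMPTY_EVENTS, blinks=EMPTY_EVENTS,
                trials=None, mask=None):
    trials = trials if trials is not None else trial_row()
    mask = mask if mask is not None else all_false_mask(samples)
    return extract_parameters(samples, mask, events, blinks, trials)


def pick(binned, parameter, b):
    rows = binned[(binned["parameter"] == parameter) & (binned["bin"] == b)]
    assert len(rows) == 1
    return rows.iloc[0]


class TestEventRate:
    def test_one_onset_gives_2hz(self):
        assert event_rate_per_bin([2700.0], (2600.0, 3100.0)) == 2.0

    def test_zero_onsets(self):
        assert event_rate_per_bin([], (0.0, 500.0)) == 0.0

    def test_half_open_boundaries(self):
        # 1 sample (4 ms) before bin start -> not counted; exactly at start
        # -> counted; exactly at end -> not counted
        assert event_rate_per_bin([496.0], (500.0, 1000.0)) == 0.0
        assert event_rate_per_bin([500.0], (500.0, 1000.0)) == 2.0
        assert event_rate_per_bin([1000.0], (500.0, 1000.0)) == 0.0


class TestBinnedValues:
    def test_zero_disparity(self):
        binned = run_extract(flat_trial_samples())
        assert pick(binned, "fixation_disparity", 1)["raw"] == 0.0

    def test_convergent_eyes_negative(self):
        s = flat_trial_samples()
        s["rx_px"] = s["lx_px"] - 10.0  # right gaze left of left gaze
        binned = run_extract(s)
        val = pick(binned, "fixation_disparity", 1)["raw"]
        assert val == pytest.approx(-10.0 * MM_PER_PX)

    def test_disparity_median_matches_sort_oracle(self):
        s = flat_trial_samples()
        # plant 5 known disparities in bin 1 (2600-3100 ms), rest eligible too
        offsets_px = np.zeros(len(s))
        vals = [3.0, -1.0, 7.0, 0.0, 2.0]
        idx = [660, 670, 680, 690, 700]  # within bin 1
        # restrict eligibility to exactly those 5 samples using a saccade
        # event covering the rest of the bin
        offsets_px[idx] = vals
        s["rx_px"] = s["lx_px"] + offsets_px
        events = event_table([("saccade", 2600.0, 2636.0),
                              ("saccade", 2804.0, 3096.0)])
        # eligible samples in bin: indices 660..700 (2640..2800 ms)
        binned = run_extract(s, events=events)
        med_px = np.median(np.concatenate(
            [vals, np.zeros(701 - 660 + 1 - len(vals))]))
        assert pick(binned, "fixation_disparity", 1)["raw"] == pytest.approx(
            med_px * MM_PER_PX)

    def test_pupil_median_and_event_exclusion(self):
        s = flat_trial_samples()
        pupil = np.full(len(s), 4.0)
        # samples within a saccade get absurd values; they must be excluded
        pupil[650:700] = 9.0
        s["l_pupil_mm"] = pupil
        s["r_pupil_mm"] = pupil
        events = event_table([("saccade", 650 * 4.0, 699 * 4.0)])
        binned = run_extract(s, events=events)
        assert pick(binned, "pupil_diameter", 1)["raw"] == 4.0

    def test_gaze_at_center_counting(self):
        s = flat_trial_samples()
        # bin 1 covers samples 650..774 (125 samples); move 100 of them away
        far = 2.0 * PX_PER_DEG  # 2 deg off-center
        for col in ("lx_px", "rx_px"):
            s.loc[675:774, col] = 960.0 + far  # label slice: 100 samples
        binned = run_extract(s)
        assert pick(binned, "gaze_at_center", 1)["raw"] == pytest.approx(20.0)

    def test_bin_fully_masked_gives_zero_pct(self):
        s = flat_trial_samples()
        mask = all_false_mask(s)
        mask.loc[650:774, "blink"] = True
        binned = run_extract(s, mask=mask)
        assert pick(binned, "gaze_at_center", 1)["raw"] == 0.0

    def test_gaze_at_center_bounded(self, session_data):
        samples, mask = session_data["samples"], session_data["mask"]
        binned = extract_parameters(samples, mask, EMPTY_EVENTS,
                                    session_data["blinks"],
                                    session_data["trials"])
        vals = binned.loc[binned["parameter"] == "gaze_at_center", "raw"]
        assert ((vals >= 0) & (vals <= 100)).all()

    def test_bins_contain_125_samples(self):
        s = flat_trial_samples()
        t = s["time_ms"].to_numpy()
        for start, end in BinningConfig().bins:
            n = np.sum((t >= 2600 + start) & (t < 2600 + end))
            assert n == 125


class TestBaseline:
    def test_bin_equal_to_baseline_corrects_to_zero(self):
        binned = run_extract(flat_trial_samples())
        for b in range(4):
            row = pick(binned, "pupil_diameter", b)
            assert row["corrected"] == 0.0

    def test_pupil_baseline_median_oracle(self):
        s = flat_trial_samples()
        pupil = np.full(len(s), 4.0)
        # baseline window is 1500-2000 ms = samples 375..499
        rng = np.random.default_rng(0)
        window_vals = 4.0 + rng.normal(0, 0.3, 125)
        pupil[375:500] = window_vals
        s["l_pupil_mm"] = pupil
        s["r_pupil_mm"] = pupil
        binned = run_extract(s)
        row = pick(binned, "pupil_diameter", 0)
        assert row["baseline"] == pytest.approx(
            np.median(np.sort(window_vals)))

    def test_blink_rate_baseline_from_sign_window(self):
        s = flat_trial_samples()
        blinks = event_table([("blink", 100.0, 200.0),
                              ("blink", 900.0, 1000.0),
                              ("blink", 1800.0, 1900.0)])
        binned = run_extract(s, blinks=blinks)
        row = pick(binned, "blink_rate", 1)
        assert row["baseline"] == pytest.approx(1.5)  # 3 onsets / 2 s
        assert row["corrected"] == pytest.approx(0.0 - 1.5)

    def test_rate_conservation_over_bins(self):
        s = flat_trial_samples()
        onsets = [2620.0, 2890.0, 3120.0, 3130.0, 4000.0]
        events = event_table([("saccade", on, on + 20.0) for on in onsets])
        binned = run_extract(s, events=events)
        rates = binned[binned["parameter"] == "saccade_rate"]
        total = (rates["raw"] / 2.0).sum()
        in_window = sum(2100.0 <= on < 4100.0 for on in onsets)
        assert total == pytest.approx(in_window)

    def test_stationary_trial_corrected_mean_near_zero(self):
        """On a stationary synthetic signal (no task ramp, no events),
        corrected pupil averages to ~0 across seeds."""
        cfg = SimulationConfig(microsaccade_rate=0, saccade_rate_idc=0,
                               blink_rate=0, pupil_task_gain=0.0)
        vals = []
        for seed in range(30):
            s = flat_trial_samples()
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 0.05, len(s))
            s["l_pupil_mm"] = 4.0 + noise
            s["r_pupil_mm"] = 4.0 + noise
            binned = run_extract(s)
            vals.extend(binned.loc[binned["parameter"] == "pupil_diameter",
                                   "corrected"])
        se = 0.05 / np.sqrt(125) * np.sqrt(2)  # two medians per value
        assert abs(np.mean(vals)) < 3 * se / np.sqrt(len(vals)) * 10


class TestDistractorEpochs:
    def test_trial_without_distractor_rejected(self):
        s = flat_trial_samples()
        with pytest.raises(MissingDistractorError):
            distractor_locked_epochs(s, all_false_mask(s), EMPTY_EVENTS,
                                     EMPTY_EVENTS, trial_row())

    def test_pupil_step_recovered(self):
        n = 1600
        s = make_samples(np.full(n, 960.0))
        onset = 2600.0 + 1500.0
        pupil = np.where(s["time_ms"] >= onset, 4.2, 4.0)
        s["l_pupil_mm"] = pupil
        s["r_pupil_mm"] = pupil
        trials = trial_row(condition="mult_distractor", block="distractor",
                           distractor_onset=onset, rt=3500.0)
        epochs = distractor_locked_epochs(s, all_false_mask(s), EMPTY_EVENTS,
                                          EMPTY_EVENTS, trials)
        post = epochs[(epochs["parameter"] == "pupil_diameter")
                      & (epochs["bin"] > 0)]
        assert np.allclose(post["corrected"], 0.2)

    def test_epoch_bins_tile_window(self):
        n = 1600
        s = make_samples(np.full(n, 960.0))
        trials = trial_row(condition="mult_distractor", block="distractor",
                           distractor_onset=2600.0 + 1500.0, rt=3500.0)
        epochs = distractor_locked_epochs(s, all_false_mask(s), EMPTY_EVENTS,
                                          EMPTY_EVENTS, trials)
        bins = epochs[["bin", "bin_start_ms", "bin_end_ms"]].drop_duplicates()
        starts = sorted(bins["bin_start_ms"])
        ends = sorted(bins["bin_end_ms"])
        assert starts == [-500.0, 0.0, 500.0]
        assert ends == [0.0, 500.0, 1000.0]


class TestCorrelations:
    @staticmethod
    def _long_from_arrays(**cols):
        n = len(next(iter(cols.values())))
        rows = []
        for i in range(n):
            for name, arr in cols.items():
                rows.append({"participant": 0, "trial": i, "bin": 0,
                             "parameter": name, "corrected": arr[i]})
        return pd.DataFrame(rows)

    def test_self_correlation_unity_and_symmetry(self, session_data):
        from oculoflow.config import DetectionConfig
        from oculoflow.events import detect_saccades
        samples, mask = session_data["samples"], session_data["mask"]
        events = detect_saccades(samples, mask, DetectionConfig())
        binned = extract_parameters(samples, mask, events,
                                    session_data["blinks"],
                                    session_data["trials"])
        corr = parameter_correlations(binned)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)
        assert np.allclose(corr.to_numpy(), corr.to_numpy().T,
                           equal_nan=True)

    def test_duplicated_column_gives_unit_offdiagonal(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 50)
        long = self._long_from_arrays(pupil_diameter=x, fixation_disparity=x)
        corr = parameter_correlations(long)
        assert corr.loc["pupil_diameter", "fixation_disparity"] == \
            pytest.approx(1.0)

    def test_constructed_r_recovered(self):
        # empirically orthogonalized construction: sample r is 0.5 exactly
        rng = np.random.default_rng(1)
        n = 10_000
        z1 = rng.normal(0, 1, n)
        z2 = rng.normal(0, 1, n)
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= (z1 @ z2 / (z1 @ z1)) * z1
        z2 /= z2.std()
        y = 0.5 * z1 + np.sqrt(1 - 0.25) * z2
        long = self._long_from_arrays(pupil_diameter=z1, fixation_disparity=y)
        corr = parameter_correlations(long)
        assert corr.loc["pupil_diameter", "fixation_disparity"] == \
            pytest.approx(0.5, abs=1e-9)

    def test_too_few_observations_raise(self):
        long = self._long_from_arrays(pupil_diameter=[1.0, 2.0],
                                      fixation_disparity=[1.0, 2.0])
        with pytest.raises(ValueError):
            parameter_correlations(long)
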