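"""End-to-end pipeline: simulate -> preprocess -> detect -> extract ->
filter -> stats, with every intermediate artifact written to the output
directory and a run log carrying the seed, the full configuration and its
hash. Re-running with an identical configuration reproduces byte-identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import io as ofio
from .config import RunConfig
from .events import detect_saccades
from .parameters import extract_parameters, parameter_correlations
from .preprocess import preprocess_samples
from .simulate import simulate_study
from .stats import compare_conditions, performance_ttests, rm_anova_2way
from .trials import assemble_conditions, filter_trials, performance_summary

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir=None) -> Path:
    """Execute the full pipeline under ``config``; returns the results dir."""
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if sim.seed != config.seed:
        sim = type(sim)(**{**sim.__dict__, "seed": config.seed})

    logger.info("simulating %d participants (seed %d)",
                sim.n_participants, sim.seed)
    samples, trials, truth = _stage("simulate")(simulate_study)(sim)
    ofio.write_samples(samples, out / "samples.csv")
    ofio.write_trials(trials, out / "trials.csv")
    ofio.write_events(truth, out / "truth_events.csv")

    logger.info("preprocessing %d samples", len(samples))
    mask, blinks, discard = _stage("preprocess")(preprocess_samples)(
        samples, config.exclusion, sim.mm_per_px)
    mask.to_csv(out / "mask.csv", index=False)
    ofio.write_events(blinks, out / "blinks.csv")
    discard.to_csv(out / "discard_summary.csv", index=False)

    logger.info("detecting events")
    events = _stage("detect")(detect_saccades)(
        samples, mask, config.detection, sim.sampling_rate,
        sim.px_per_deg, sim.screen_center)
    ofio.write_events(events, out / "detected_events.csv")

    logger.info("extracting binned parameters")
    binned = _stage("extract")(extract_parameters)(
        samples, mask, events, blinks, trials, config.binning,
        config.baseline, sim.px_per_deg, sim.mm_per_px, sim.screen_center)
    binned.to_csv(out / "binned_parameters.csv", index=False)

    logger.info("filtering trials")
    included, report = _stage("filter")(filter_trials)(trials)
    report.to_csv(out / "exclusion_report.csv", index=False)
    perf = performance_summary(trials)
    perf.to_csv(out / "performance_summary.csv", index=False)
    cells, flags = assemble_conditions(included, binned)
    cells.to_csv(out / "condition_cells.csv", index=False)
    flags.to_csv(out / "cell_flags.csv", index=False)

    logger.info("statistics")
    stats_dir = out
    perf_tests = _stage("stats")(performance_ttests)(perf, config.bayes)
    perf_tests.to_csv(stats_dir / "performance_ttests.csv", index=False)
    eye_tests = _stage("stats")(compare_conditions)(
        cells, "mult_no_distractor", "mult_distractor", 4, config.bayes)
    eye_tests.to_csv(stats_dir / "eye_parameter_ttests.csv", index=False)

    anova_rows = []
    for param, grp in cells.groupby("parameter"):
        data = grp.rename(columns={"bin": "time", "corrected": "value"})
        try:
            res = _stage("stats")(rm_anova_2way)(
                data, dv="value", within=("condition", "time"),
                subject="participant")
        except PipelineError as exc:
            logger.warning("ANOVA skipped for %s: %s", param, exc)
            continue
        tab = res.table.copy()
        tab.insert(0, "parameter", param)
        anova_rows.append(tab)
    anova = (pd.concat(anova_rows, ignore_index=True) if anova_rows
             else pd.DataFrame())
    anova.to_csv(stats_dir / "anova.csv", index=False)

    try:
        corr = parameter_correlations(
            binned[[tuple(x) in set(map(tuple,
                    included[["participant", "trial"]].to_numpy()))
                    for x in binned[["participant", "trial"]].to_numpy()]])
        corr.to_csv(stats_dir / "parameter_correlations.csv")
    except ValueError as exc:
        logger.warning("correlations skipped: %s", exc)

    log = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": config.to_dict(),
        "versions": _versions(),
        "n_participants": int(sim.n_participants),
        "n_trials": int(len(trials)),
        "n_samples": int(len(samples)),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    logger.info("pipeline complete: %s", out)
    return out


def _versions() -> dict:
    import numpy, pandas, pingouin, scipy  # noqa: PLC0415
    from . import __version__
    return {"oculoflow": __version__, "numpy": numpy.__version__,
            "scipy": scipy.__version__, "pandas": pandas.__version__,
            "pingouin": pingouin.__version__}
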