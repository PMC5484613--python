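"""Reproducible experiment plumbing: config, tabular I/O, pipeline runner.

File conventions (all CSV, header row, floats at 9 significant digits,
0-based frame indices, times in ms, luminance in cd/m^2):

* trials file (long): trial_id, branch_label, frame_index,
  luminance_cdm2, generative_mean_cdm2 — with a companion ``*_meta.csv``
  holding target path, difficulty indices, offsets and frame timing;
* results file: trial_id, model_name, choice_l1..l3, correct_l1..l3,
  rt_ms, terminated_by_bound, seed;
* activity file (long): trial_id, alternative_label, time_ms, activity.

``run_experiment`` executes generate -> simulate -> analyses from a
single validated config and writes a manifest with checksums so that
identical configs are verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accumulator_models as am
from . import activity_analysis as aa
from . import psychophysics_analysis as pa
from .accumulator_models import MODEL_NAMES, PARAM_CLASSES, SimResult, batch_simulate
from .task_stimuli import LuminanceTrial, TreeTaskSpec, generate_trials, make_tree_task

FLOAT_FMT = "%.9g"

__version__ = "0.1.0"

_TRIAL_COLS = ["trial_id", "branch_label", "frame_index", "luminance_cdm2", "generative_mean_cdm2"]
_META_COLS = [
    "trial_id", "n_levels", "sample_period_ms",
    "target_l1", "target_l2", "target_l3",
    "difficulty_l1", "difficulty_l2", "difficulty_l3",
    "offset_l1", "offset_l2", "offset_l3",
]
_RESULT_COLS = [
    "trial_id", "model_name", "choice_l1", "choice_l2", "choice_l3",
    "correct_l1", "correct_l2", "correct_l3", "rt_ms", "terminated_by_bound", "seed",
]

_ANALYSES = ("kernel", "psychometric", "conditional", "rt", "seriality", "quartile", "growth")


class SchemaError(ValueError):
    """A tabular file does not match its declared schema."""


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_TASK_KEYS = {
    "n_levels", "samples_per_trial", "sample_period", "noise_sd", "background_lum",
    "difficulty_levels", "min_view_time", "distractor_mean_lum", "target_mean_lum",
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Validated experiment definition: task + model + analyses + seed."""

    task: dict[str, Any]
    model_name: str
    model_params: dict[str, Any]
    analyses: tuple[dict[str, Any], ...]
    n_trials: int
    seed: int
    output_dir: str

    def task_spec(self) -> TreeTaskSpec:
        return make_tree_task(**self.task)

    def params(self):
        return PARAM_CLASSES[self.model_name](**self.model_params)

    def to_dict(self) -> dict[str, Any]:
        return {
            "task": dict(self.task),
            "model": {"name": self.model_name, "params": dict(self.model_params)},
            "analyses": [dict(a) for a in self.analyses],
            "n_trials": self.n_trials,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def config_from_dict(raw: dict[str, Any]) -> ExperimentConfig:
    """Validate a raw mapping; reports every problem at once."""
    problems: list[str] = []
    known_top = {"task", "model", "analyses", "n_trials", "seed", "output_dir"}
    for k in raw:
        if k not in known_top:
            problems.append(f"unknown key {k!r}")
    task = dict(raw.get("task") or {})
    for k in task:
        if k not in _TASK_KEYS:
            problems.append(f"task: unknown key {k!r}")
    if "difficulty_levels" in task and task["difficulty_levels"] is not None:
        task["difficulty_levels"] = tuple(tuple(float(v) for v in lvl) for lvl in task["difficulty_levels"])
    model = raw.get("model") or {}
    name = model.get("name")
    params = dict(model.get("params") or {})
    if name not in MODEL_NAMES:
        problems.append(f"model.name: {name!r} not in {MODEL_NAMES}")
    else:
        valid = {f for f in PARAM_CLASSES[name].__dataclass_fields__}
        for k in params:
            if k not in valid:
                problems.append(f"model.params: unknown key {k!r} for {name}")
        if name == "serial" and "stages" in params:
            params["stages"] = tuple(am.StageParams(**s) for s in params["stages"])
    analyses = raw.get("analyses") or []
    for i, a in enumerate(analyses):
        what = (a or {}).get("what")
        if what not in _ANALYSES:
            problems.append(f"analyses[{i}].what: {what!r} not in {_ANALYSES}")
    if "seed" not in raw:
        problems.append("seed: required (no implicit clock seeding)")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed: must be an integer, got {type(seed).__name__}")
        seed = 0
    n_trials = raw.get("n_trials", 0)
    if not isinstance(n_trials, int) or n_trials < 0:
        problems.append(f"n_trials: must be a non-negative integer, got {n_trials!r}")
        n_trials = 0
    try:
        make_tree_task(**task)
    except (ValueError, TypeError) as e:
        problems.append(f"task: {e}")
    if name in MODEL_NAMES and not problems:
        try:
            PARAM_CLASSES[name](**params)
        except (ValueError, TypeError) as e:
            problems.append(f"model.params: {e}")
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    return ExperimentConfig(
        task=task,
        model_name=name,
        model_params=params,
        analyses=tuple(dict(a) for a in analyses),
        n_trials=n_trials,
        seed=seed,
        output_dir=str(raw.get("output_dir", "hiertree_run")),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML experiment config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def dump_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    d = config.to_dict()
    if "difficulty_levels" in d["task"] and d["task"]["difficulty_levels"] is not None:
        d["task"]["difficulty_levels"] = [list(l) for l in d["task"]["difficulty_levels"]]
    if config.model_name == "serial" and "stages" in d["model"]["params"]:
        d["model"]["params"]["stages"] = [asdict(s) for s in d["model"]["params"]["stages"]]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Trials / results / activity I/O
# ---------------------------------------------------------------------------


def _meta_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + "_meta" + p.suffix)


def write_trials(trials: Sequence[LuminanceTrial], path: str | Path) -> None:
    """Write trials (long format) plus the companion metadata CSV."""
    rows = []
    meta_rows = []
    for t in trials:
        for b in t.samples:
            for k, (lum, mean) in enumerate(zip(t.samples[b], [t.generative_means[b]] * len(t.samples[b]))):
                rows.append((t.trial_id, b, k, lum, mean))
        lab = t.difficulty_label
        meta_rows.append({
            "trial_id": t.trial_id,
            "n_levels": t.n_levels,
            "sample_period_ms": t.sample_period,
            "target_l1": t.target_path[0],
            "target_l2": t.target_path[1],
            "target_l3": t.target_path[2] if t.n_levels == 3 else "",
            "difficulty_l1": "" if lab is None else lab[0],
            "difficulty_l2": "" if lab is None else lab[1],
            "difficulty_l3": "" if lab is None or t.n_levels < 3 else lab[2],
            "offset_l1": t.offsets[0],
            "offset_l2": t.offsets[1],
            "offset_l3": t.offsets[2] if t.n_levels == 3 else "",
        })
    pd.DataFrame(rows, columns=_TRIAL_COLS).to_csv(path, index=False, float_format=FLOAT_FMT)
    pd.DataFrame(meta_rows, columns=_META_COLS).to_csv(_meta_path(path), index=False, float_format=FLOAT_FMT)


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_trials(path: str | Path) -> list[LuminanceTrial]:
    """Read trials written by :func:`write_trials` (lossless round-trip)."""
    df = pd.read_csv(path)
    _check_columns(df, _TRIAL_COLS, "trials file")
    meta = pd.read_csv(_meta_path(path), dtype={"target_l3": str, "difficulty_l3": str})
    _check_columns(meta, _META_COLS, "trials metadata file")
    trials = []
    grouped = dict(tuple(df.sort_values(["trial_id", "branch_label", "frame_index"]).groupby("trial_id")))
    for row in meta.itertuples():
        tid = int(row.trial_id)
        if tid not in grouped:
            raise SchemaError(f"trials file: trial {tid} in metadata but absent from samples")
        g = grouped[tid]
        samples = {}
        means = {}
        for b, gb in g.groupby("branch_label"):
            gb = gb.sort_values("frame_index")
            if not np.array_equal(gb["frame_index"].to_numpy(), np.arange(len(gb))):
                raise SchemaError(f"trials file: non-contiguous frame_index for trial {tid} branch {b}")
            samples[str(b)] = gb["luminance_cdm2"].to_numpy(dtype=float)
            means[str(b)] = float(gb["generative_mean_cdm2"].iloc[0])
        n_levels = int(row.n_levels)
        path_t = [str(row.target_l1), str(row.target_l2)]
        if n_levels == 3:
            path_t.append(str(row.target_l3))
        def _blank(v):
            return v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == "" or str(v) == "nan"
        if _blank(row.difficulty_l1):
            lab = None
        else:
            lab = [int(float(row.difficulty_l1)), int(float(row.difficulty_l2))]
            if n_levels == 3:
                lab.append(int(float(row.difficulty_l3)))
            lab = tuple(lab)
        offs = [float(row.offset_l1), float(row.offset_l2)]
        if n_levels == 3:
            offs.append(float(row.offset_l3))
        trials.append(LuminanceTrial(
            trial_id=tid, samples=samples, target_path=tuple(path_t),
            difficulty_label=lab, offsets=tuple(offs), generative_means=means,
            sample_period=float(row.sample_period_ms),
        ))
    return trials


def write_results(results: Sequence[SimResult], path: str | Path) -> None:
    """Write simulation results (one row per trial)."""
    rows = []
    for r in results:
        c3 = r.choice_per_level[2] if len(r.choice_per_level) > 2 else ""
        k3 = r.correct_per_level[2] if len(r.correct_per_level) > 2 else ""
        rows.append({
            "trial_id": r.trial_id, "model_name": r.model_name,
            "choice_l1": r.choice_per_level[0], "choice_l2": r.choice_per_level[1],
            "choice_l3": c3,
            "correct_l1": r.correct_per_level[0], "correct_l2": r.correct_per_level[1],
            "correct_l3": k3,
            "rt_ms": r.rt, "terminated_by_bound": r.terminated_by_bound, "seed": r.seed,
        })
    pd.DataFrame(rows, columns=_RESULT_COLS).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_results(path: str | Path) -> list[SimResult]:
    """Read results written by :func:`write_results`."""
    df = pd.read_csv(path, dtype={"choice_l3": str, "correct_l3": str})
    _check_columns(df, _RESULT_COLS, "results file")
    out = []
    for row in df.itertuples():
        choices = [str(row.choice_l1), str(row.choice_l2)]
        correct = [bool(row.correct_l1), bool(row.correct_l2)]
        c3 = "" if (isinstance(row.choice_l3, float) and np.isnan(row.choice_l3)) else str(row.choice_l3)
        if c3 not in ("", "nan"):
            choices.append(c3)
            correct.append(str(row.correct_l3) == "True")
        out.append(SimResult(
            trial_id=int(row.trial_id), model_name=str(row.model_name),
            choice_per_level=tuple(choices), correct_per_level=tuple(correct),
            rt=float(row.rt_ms), terminated_by_bound=bool(row.terminated_by_bound),
            seed=int(row.seed),
        ))
    return out


def write_activity(results: Sequence[SimResult], path: str | Path) -> None:
    """Write activity traces in long format (may be large)."""
    frames = []
    for r in results:
        if r.activity is None:
            continue
        for label, trace in r.activity.items():
            frames.append(pd.DataFrame({
                "trial_id": r.trial_id,
                "alternative_label": label,
                "time_ms": r.activity_times,
                "activity": trace,
            }))
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["trial_id", "alternative_label", "time_ms", "activity"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_activity(path: str | Path, results: Sequence[SimResult]) -> list[SimResult]:
    """Attach activity traces from an activity CSV onto results (by trial id)."""
    df = pd.read_csv(path)
    _check_columns(df, ["trial_id", "alternative_label", "time_ms", "activity"], "activity file")
    by_id = {r.trial_id: r for r in results}
    for tid, g in df.groupby("trial_id"):
        r = by_id.get(int(tid))
        if r is None:
            raise SchemaError(f"activity file: trial {tid} not present in results")
        acts = {}
        times = None
        for label, gl in g.groupby("alternative_label"):
            gl = gl.sort_values("time_ms")
            acts[str(label)] = gl["activity"].to_numpy(dtype=float)
            times = gl["time_ms"].to_numpy(dtype=float)
        r.activity = acts
        r.activity_times = times
    return results


# ---------------------------------------------------------------------------
# Pipeline runner
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Checksummed record of one pipeline run."""

    config_hash: str
    version: str
    files: dict[str, str]
    started: float
    finished: float
    analysis_errors: dict[str, str] = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _make_run_logger(log_path: Path) -> logging.Logger:
    logger = logging.Logger(f"hiertree.run.{log_path}")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    return logger


def run_experiment(config: ExperimentConfig) -> RunManifest:
    """Execute generate -> simulate -> analyses and write all outputs.

    Generation or simulation failures abort with the stage name;
    analysis-stage failures (e.g. empty input with n_trials = 0) are
    recorded in the run log and manifest and do not abort the run.
    """
    started = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = _make_run_logger(out / "run.log")
    logger.info("config seed=%d n_trials=%d model=%s", config.seed, config.n_trials, config.model_name)

    spec = config.task_spec()
    needs_activity = any(a["what"] in ("quartile", "growth") for a in config.analyses)

    t0 = time.time()
    try:
        trials = generate_trials(spec, config.n_trials, config.seed)
        write_trials(trials, out / "trials.csv")
    except Exception as e:
        logger.error("stage generate failed: %s", e)
        raise RuntimeError(f"stage generate failed: {e}") from e
    logger.info("stage generate: %d trials in %.2fs", len(trials), time.time() - t0)

    t0 = time.time()
    try:
        params = config.params()
        results = batch_simulate(trials, config.model_name, params, config.seed,
                                 record_activity=needs_activity)
        write_results(results, out / "results.csv")
        if needs_activity:
            write_activity(results, out / "activity.csv")
    except Exception as e:
        logger.error("stage simulate failed: %s", e)
        raise RuntimeError(f"stage simulate failed: {e}") from e
    logger.info("stage simulate: model=%s in %.2fs", config.model_name, time.time() - t0)

    errors: dict[str, str] = {}
    for i, a in enumerate(config.analyses):
        what = a["what"]
        tag = f"{i}_{what}"
        t0 = time.time()
        try:
            _run_analysis(a, spec, trials, results, out, config.seed)
            logger.info("analysis %s done in %.2fs", tag, time.time() - t0)
        except Exception as e:
            errors[tag] = str(e)
            logger.error("analysis %s failed: %s", tag, e)

    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    config_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()
    files = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix == ".csv"
    }
    manifest = RunManifest(
        config_hash=config_hash, version=__version__, files=files,
        started=started, finished=time.time(), analysis_errors=errors,
    )
    (out / "manifest.json").write_text(json.dumps({
        "config_hash": manifest.config_hash,
        "version": manifest.version,
        "files": manifest.files,
        "started": manifest.started,
        "finished": manifest.finished,
        "analysis_errors": manifest.analysis_errors,
    }, indent=2))
    logger.info("run complete; %d analysis error(s)", len(errors))
    return manifest


def _kernel_frame(k: pa.KernelEstimate) -> pd.DataFrame:
    return pd.DataFrame({
        "frame_index": np.arange(len(k.weights)),
        "time_ms": k.frame_times,
        "weight": k.weights,
        "ci_low": k.ci_low,
        "ci_high": k.ci_high,
    })


def _run_analysis(a, spec, trials, results, out: Path, seed: int) -> None:
    what = a["what"]
    if len(trials) == 0:
        raise ValueError(f"analysis {what}: empty input (0 trials)")
    if what == "kernel":
        k = pa.estimate_kernel(trials, results, level=a.get("level", 1),
                               alignment=a.get("alignment", "stimulus_onset"),
                               n_boot=a.get("n_boot", 1000), seed=seed)
        _kernel_frame(k).to_csv(out / f"kernel_l{k.level}_{k.alignment}.csv",
                                index=False, float_format=FLOAT_FMT)
    elif what == "psychometric":
        x = [pa.l2_signed_evidence(t) for t in trials]
        y = [1 if r.choice_per_level[1] == "up" else 0 for r in results]
        fit = pa.fit_psychometric(x, y, a.get("lapse_mode", "fixed"))
        pd.DataFrame([asdict(fit)]).to_csv(out / "psychometric.csv", index=False, float_format=FLOAT_FMT)
    elif what == "conditional":
        cp = pa.conditional_psychometric(trials, results, n_boot=a.get("n_boot", 1000), seed=seed)
        pd.DataFrame([{
            "slope_l1_correct": cp.fit_given_l1_correct.slope,
            "slope_l1_error": cp.fit_given_l1_error.slope,
            "slope_ratio": cp.slope_ratio,
            "ratio_ci_low": cp.ratio_ci[0],
            "ratio_ci_high": cp.ratio_ci[1],
            "l2_acc_given_l1_correct": cp.accuracy_given_l1_correct,
            "l2_acc_given_l1_error": cp.accuracy_given_l1_error,
        }]).to_csv(out / "conditional.csv", index=False, float_format=FLOAT_FMT)
    elif what == "rt":
        labels = [t.difficulty_label[0] if t.difficulty_label else None for t in trials]
        rt = pa.rt_by_difficulty(results, labels)
        rt.table.to_csv(out / "rt_by_difficulty.csv", index=False, float_format=FLOAT_FMT)
    elif what == "seriality":
        align = a.get("alignment", "stimulus_onset")
        nb = a.get("n_boot", 200)
        k1 = pa.estimate_kernel(trials, results, a.get("level_a", 1), align, nb, seed)
        k2 = pa.estimate_kernel(trials, results, a.get("level_b", 2), align, nb, seed)
        s = pa.kernel_seriality(k1, k2)
        pd.DataFrame([{"overlap": s.overlap, "com_offset_ms": s.com_offset}]).to_csv(
            out / "seriality.csv", index=False, float_format=FLOAT_FMT)
    elif what == "quartile":
        qt = aa.quartile_condition(trials, results,
                                   correct_only=a.get("correct_only", True),
                                   window=tuple(a.get("window", (200.0, 500.0))), seed=seed)
        pd.DataFrame([
            {"branch": b, "slope": s, "se": se, "n": sum(v for (d, q), v in qt.n_per_cell.items())}
            for b, (s, se) in sorted(qt.window_stat.items())
        ]).to_csv(out / "quartile_slopes.csv", index=False, float_format=FLOAT_FMT)
        rows = []
        for (b, q), trace in sorted(qt.quartile_means.items()):
            for t, v in zip(qt.times, trace):
                rows.append((b, q, t, v))
        pd.DataFrame(rows, columns=["branch", "quartile", "time_ms", "mean_activity"]).to_csv(
            out / "quartile_traces.csv", index=False, float_format=FLOAT_FMT)
    elif what == "growth":
        branch = a.get("branch", "TT")
        window = tuple(a.get("window", (spec.min_view_time, spec.trial_duration)))
        traces = [r.activity[branch] for r in results if r.activity is not None]
        if not traces:
            raise ValueError("growth analysis: no activity traces")
        mean_trace = np.mean(traces, axis=0)
        fit = aa.exponential_growth_test(mean_trace, results[0].activity_times, window)
        pd.DataFrame([asdict(fit)]).to_csv(out / "growth.csv", index=False, float_format=FLOAT_FMT)
    else:
        raise ValueError(f"unknown analysis {what!r}")
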