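"""Synthetic wearable physiology campaigns with known ground truth.

Emulates the measurement structure of a multi-deployment simulated-EVA
campaign: 1 Hz chest-strap streams of heart rate, respiration rate and HRV
for each (participant, deployment, EVA), together with minute-resolution
task logs.  Every generated second has a known true task label and a known
expected level, so downstream stages (annotation, filtering, aggregation,
case pooling, bootstrap inference) can be tested by parameter recovery.

The signal model for each parameter is additive:

    value(t) = baseline_mu[participant] + task_effect[task(t)]
               + carryover(t) + AR(1) noise

where ``carryover`` is an exponentially decaying residue of the most recent
strenuous task (translation or rock breaking), with configurable half-life,
and the AR(1) noise has stationary standard deviation ``noise_sd``.
Measurement realism knobs: per-second HR-confidence dropouts (confidence
drawn below 50%), an HRV warm-up gap at stream start, and task-log
transition times jittered and rounded to whole minutes.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .constants import BASE, DEPLOYMENTS, PARAMETERS, STRENUOUS_TASKS, TASK_CODES
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

STREAM_COLUMNS = ["time_s", "hr_bpm", "rr_brpm", "hrv_ms", "hr_confidence"]
LOG_COLUMNS = ["time_s", "participant", "task_code", "note"]
MANIFEST_COLUMNS = [
    "participant",
    "deployment",
    "eva",
    "stream_path",
    "log_path",
    "clock_offset_s",
]

# Default per-task additive shifts relative to baseline rest, in parameter
# units (bpm, breaths/min, ms).  Strenuous field tasks (translation,
# breaking rocks) shift HR/RR most; HRV drops under load, so its shifts are
# negative.  Baseline carries no shift by construction.
DEFAULT_TASK_EFFECT: dict[str, dict[str, float]] = {
    "Base": {"HR": 0.0, "RR": 0.0, "HRV": 0.0},
    "ET": {"HR": 28.0, "RR": 4.5, "HRV": -14.0},
    "BR": {"HR": 26.0, "RR": 4.0, "HRV": -13.0},
    "BS": {"HR": 18.0, "RR": 2.5, "HRV": -9.0},
    "EO": {"HR": 12.0, "RR": 2.0, "HRV": -6.0},
    "EI": {"HR": 10.0, "RR": 1.5, "HRV": -5.0},
}

DEFAULT_NOISE_SD: dict[str, float] = {"HR": 3.0, "RR": 1.5, "HRV": 8.0}

# Resting-level ranges used when per-participant baselines are not given:
# (low, high) per parameter, sampled uniformly per participant.
_BASELINE_RANGES: dict[str, tuple[float, float]] = {
    "HR": (62.0, 82.0),
    "RR": (12.0, 17.0),
    "HRV": (45.0, 75.0),
}

# Physiological floors applied after noise.
_FLOORS: dict[str, float] = {"HR": 30.0, "RR": 4.0, "HRV": 1.0}


def _default_deployment_plan(n_participants: int) -> tuple[tuple[str, ...], ...]:
    """Study-shaped rotation: 2 participants in all three deployments, 2 in
    two, and the rest in a single deployment (14 participant-deployment
    pairs for 8 participants)."""
    singles = ("HI1", "ID", "HI2", "HI2", "ID", "HI1")
    plan: list[tuple[str, ...]] = []
    for i in range(n_participants):
        if i < 2:
            plan.append(("ID", "HI1", "HI2"))
        elif i < 4:
            plan.append(("ID", "HI1"))
        else:
            plan.append((singles[(i - 4) % len(singles)],))
    return tuple(plan)


@dataclass
class ScenarioConfig:
    """Everything needed to generate one campaign deterministically.

    Parameters
    ----------
    n_participants
        Number of crewmembers (default 8).
    deployments_per_participant
        Per-participant tuple of deployment codes; ``None`` uses the default
        rotation (two participants in all three deployments, two in two,
        the rest in one), which with ``evas_per_deployment=2`` yields 28
        streams.
    evas_per_deployment
        Simulated EVAs per (participant, deployment).
    task_schedule_template
        ``"auto"`` for a realistic schedule (baseline rest, traverse/observe
        alternation, then instrument/sampling blocks), or an explicit ordered
        list of ``(task_code, duration_s)``.
    baseline_mu
        ``{parameter: [level per participant]}`` or ``None`` to draw resting
        levels per participant from realistic ranges.
    task_effect
        ``{task: {parameter: shift}}`` additive shifts over baseline.
    deployment_shift
        Optional ``{deployment: {parameter: shift}}`` additive level shift,
        for scenarios where a participant's physiology genuinely differs
        between field campaigns (drives case splitting); ``None`` means no
        shift.
    carryover_halflife_s
        Half-life of the decaying residue left by a strenuous task; ``0``
        disables carry-over.
    ar1_rho
        Lag-1 autocorrelation of the per-second noise, in ``[0, 1)``.
    noise_sd
        Stationary noise SD per parameter (same units as the parameter).
    noise_dist
        ``"normal"`` or ``"lognormal"`` (standardized, right-skewed) noise.
    dropout_rate
        Per-second probability that HR confidence is drawn below 50%.
    hrv_warmup_s
        Seconds of missing HRV at the start of every stream.
    label_jitter_s
        Maximum absolute shift applied to logged transition times before
        rounding them to whole minutes; ``0`` keeps the log exact.
    seed
        Campaign seed; identical config + seed reproduces every file.
    """

    n_participants: int = 8
    deployments_per_participant: tuple[tuple[str, ...], ...] | None = None
    evas_per_deployment: int = 2
    task_schedule_template: str | Sequence[tuple[str, int]] = "auto"
    baseline_mu: Mapping[str, Sequence[float]] | None = None
    task_effect: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(v) for t, v in DEFAULT_TASK_EFFECT.items()}
    )
    deployment_shift: Mapping[str, Mapping[str, float]] | None = None
    carryover_halflife_s: float = 60.0
    ar1_rho: float = 0.9
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    noise_dist: str = "normal"
    dropout_rate: float = 0.05
    hrv_warmup_s: int = 120
    label_jitter_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def deployment_plan(self) -> tuple[tuple[str, ...], ...]:
        if self.deployments_per_participant is not None:
            return tuple(tuple(d) for d in self.deployments_per_participant)
        return _default_deployment_plan(self.n_participants)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.evas_per_deployment < 1:
            raise ConfigurationError("evas_per_deployment must be >= 1")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ConfigurationError(f"ar1_rho must lie in [0, 1), got {self.ar1_rho}")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ConfigurationError(
                f"dropout_rate must lie in [0, 1], got {self.dropout_rate}"
            )
        if self.label_jitter_s < 0 or self.hrv_warmup_s < 0 or self.carryover_halflife_s < 0:
            raise ConfigurationError("jitter, warm-up and half-life must be >= 0")
        if self.noise_dist not in ("normal", "lognormal"):
            raise ConfigurationError(f"unknown noise_dist {self.noise_dist!r}")
        for task in self.task_effect:
            if task not in TASK_CODES:
                raise ConfigurationError(f"unknown task code in task_effect: {task!r}")
        if self.deployment_shift is not None:
            for code in self.deployment_shift:
                if code not in DEPLOYMENTS:
                    raise ConfigurationError(
                        f"unknown deployment code in deployment_shift: {code!r}"
                    )
        for deps in self.deployment_plan:
            for code in deps:
                if code not in DEPLOYMENTS:
                    raise ConfigurationError(f"unknown deployment code: {code!r}")
        if len(self.deployment_plan) != self.n_participants:
            raise ConfigurationError(
                "deployments_per_participant length must equal n_participants"
            )
        if self.task_schedule_template != "auto":
            schedule = list(self.task_schedule_template)
            if not schedule:
                raise ConfigurationError("task schedule is empty")
            for task, dur in schedule:
                if task not in TASK_CODES:
                    raise ConfigurationError(f"unknown task code in schedule: {task!r}")
                if dur <= 0:
                    raise ConfigurationError(
                        f"schedule durations must be > 0, got {dur} for {task}"
                    )

    def resolved_baseline_mu(self) -> dict[str, np.ndarray]:
        """Per-participant resting levels, drawn once from the campaign seed
        when not supplied explicitly."""
        if self.baseline_mu is not None:
            out = {}
            for param in PARAMETERS:
                levels = np.asarray(self.baseline_mu[param], dtype=float)
                if levels.shape != (self.n_participants,):
                    raise ConfigurationError(
                        f"baseline_mu[{param!r}] must have one level per participant"
                    )
                out[param] = levels
            return out
        rng = np.random.default_rng([int(self.seed), 987_001])
        return {
            param: rng.uniform(lo, hi, size=self.n_participants)
            for param, (lo, hi) in _BASELINE_RANGES.items()
        }


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests.

    ``true_means`` holds the additive-model level (baseline + task shift) per
    (participant, deployment, parameter, task); carry-over and noise average
    to ~0 over long occurrences.  ``intervals`` holds the exact second-level
    task spans of every EVA, before any log jitter.
    """

    true_means: pd.DataFrame
    intervals: pd.DataFrame


def _auto_schedule(deployment: str, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Baseline rest, then traverse/observe alternation, then two
    instrument-and-sampling station blocks.  Baseline is ~30 min for the
    Idaho protocol (seated rest) and ~10 min for the Hawai'i protocol
    (vehicle transit)."""
    base_s = 1800 if deployment == "ID" else 600
    schedule: list[tuple[str, int]] = [(BASE, base_s)]
    for _ in range(2):
        schedule.append(("ET", int(rng.integers(240, 481))))
        schedule.append(("EO", int(rng.integers(120, 241))))
    for _ in range(2):
        schedule.append(("ET", int(rng.integers(120, 241))))
        schedule.append(("EI", int(rng.integers(180, 301))))
        schedule.append(("BR", int(rng.integers(120, 241))))
        schedule.append(("BS", int(rng.integers(120, 301))))
    schedule.append(("EO", int(rng.integers(60, 181))))
    return schedule


def _ar1_noise(
    n: int, sd: float, rho: float, dist: str, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``; the lognormal option
    pushes standardized right-skewed innovations through the same filter."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    z0 = rng.normal(0.0, 1.0)
    innov = rng.normal(0.0, np.sqrt(1.0 - rho**2), size=n)
    z = lfilter([1.0], [1.0, -rho], innov, zi=np.array([rho * z0]))[0]
    if dist == "lognormal":
        # standardized shifted lognormal: mean 0, SD 1, skewed right
        m = np.exp(0.5)
        s = np.sqrt(np.e**2 - np.e)
        z = (np.exp(z) - m) / s
    return sd * z


def _carryover(
    schedule: list[tuple[str, int]],
    effect: Mapping[str, Mapping[str, float]],
    param: str,
    halflife: float,
) -> np.ndarray:
    """Exponentially decaying residue of the last strenuous task, added to
    every subsequent non-strenuous second until the next strenuous task."""
    total = sum(d for _, d in schedule)
    carry = np.zeros(total)
    if halflife <= 0:
        return carry
    lam = np.log(2.0) / halflife
    amp = 0.0
    t_leave = 0.0
    t = 0
    for task, dur in schedule:
        if task in STRENUOUS_TASKS:
            amp = effect[task][param]
            t_leave = t + dur
        elif amp != 0.0:
            ts = np.arange(t, t + dur, dtype=float)
            carry[t : t + dur] = amp * np.exp(-lam * (ts - t_leave))
        t += dur
    return carry


def _jitter_log(
    intervals: pd.DataFrame, jitter_s: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Transition times perturbed by U(-jitter, +jitter) then rounded to
    whole minutes; the stream-start transition stays at 0.  Transitions that
    collapse to a non-increasing time are dropped (their segment vanished)."""
    starts = intervals["start_s"].to_numpy(dtype=float)
    tasks = intervals["task_code"].to_numpy()
    jittered = starts.copy()
    if jitter_s > 0 and len(starts) > 1:
        jittered[1:] = starts[1:] + rng.uniform(-jitter_s, jitter_s, size=len(starts) - 1)
        jittered[1:] = np.rint(jittered[1:] / 60.0) * 60.0
        jittered = np.clip(jittered, 0.0, None)
    keep_t: list[float] = []
    keep_task: list[str] = []
    for t, task in zip(jittered, tasks):
        while keep_t and t <= keep_t[-1]:
            keep_t.pop()
            keep_task.pop()
        keep_t.append(float(t))
        keep_task.append(task)
    return pd.DataFrame({"time_s": np.asarray(keep_t, dtype=int), "task_code": keep_task})


def generate_eva(
    config: ScenarioConfig,
    participant: int,
    deployment: str,
    eva_index: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one EVA: the 1 Hz stream, the exact task intervals, and the
    minute-rounded jittered task log.

    Returns
    -------
    stream : DataFrame with columns ``time_s, hr_bpm, rr_brpm, hrv_ms,
        hr_confidence``, one row per second.
    true_log : DataFrame with columns ``start_s, end_s, task_code`` — the
        exact half-open task spans.
    jittered_log : DataFrame with columns ``time_s, participant, task_code,
        note`` — transition rows only, as a human minute-scale logger would
        record them.
    """
    config.validate()
    if deployment not in DEPLOYMENTS:
        raise ConfigurationError(f"unknown deployment code: {deployment!r}")
    if eva_index < 0 or eva_index >= config.evas_per_deployment:
        raise ConfigurationError(
            f"eva_index {eva_index} outside [0, {config.evas_per_deployment})"
        )
    dep_idx = DEPLOYMENTS.index(deployment)
    rng = np.random.default_rng([int(config.seed), int(participant), dep_idx, eva_index])

    if config.task_schedule_template == "auto":
        schedule = _auto_schedule(deployment, rng)
    else:
        schedule = [(t, int(d)) for t, d in config.task_schedule_template]
    total = sum(d for _, d in schedule)
    time_s = np.arange(total, dtype=int)

    starts = np.cumsum([0] + [d for _, d in schedule[:-1]])
    true_log = pd.DataFrame(
        {
            "start_s": starts.astype(int),
            "end_s": (starts + np.array([d for _, d in schedule])).astype(int),
            "task_code": [t for t, _ in schedule],
        }
    )

    baselines = config.resolved_baseline_mu()
    dep_shift = (config.deployment_shift or {}).get(deployment, {})
    task_per_sec = np.repeat([t for t, _ in schedule], [d for _, d in schedule])
    values: dict[str, np.ndarray] = {}
    for param in PARAMETERS:
        mu = baselines[param][participant - 1] + dep_shift.get(param, 0.0)
        shift = np.array(
            [config.task_effect.get(t, {}).get(param, 0.0) for t in task_per_sec]
        )
        carry = _carryover(schedule, config.task_effect, param, config.carryover_halflife_s)
        noise = _ar1_noise(
            total, float(config.noise_sd[param]), config.ar1_rho, config.noise_dist, rng
        )
        values[param] = np.maximum(mu + shift + carry + noise, _FLOORS[param])

    hrv = values["HRV"].copy()
    hrv[: min(config.hrv_warmup_s, total)] = np.nan

    confidence = rng.uniform(75.0, 100.0, size=total)
    drop = rng.random(total) < config.dropout_rate
    confidence[drop] = rng.uniform(0.0, 50.0, size=int(drop.sum()))

    stream = pd.DataFrame(
        {
            "time_s": time_s,
            "hr_bpm": np.round(values["HR"], 1),
            "rr_brpm": np.round(values["RR"], 1),
            "hrv_ms": np.round(hrv, 1),
            "hr_confidence": np.round(confidence, 0),
        }
    )

    jit = _jitter_log(true_log.rename(columns={"start_s": "start_s"}), config.label_jitter_s, rng)
    jittered_log = pd.DataFrame(
        {
            "time_s": jit["time_s"],
            "participant": participant,
            "task_code": jit["task_code"],
            "note": "",
        }
    )
    return stream, true_log, jittered_log


def generate_campaign(
    config: ScenarioConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, GroundTruth]:
    """Write a full campaign to ``out_dir`` and return (manifest, truth).

    Layout: ``streams/p<P>_<dep>_eva<k>.csv``, ``logs/p<P>_<dep>_eva<k>.csv``
    and ``manifest.csv`` at the top level (paths in the manifest are relative
    to its own directory).  The default configuration reproduces the study
    shape: 8 participants rotating over {ID, HI1, HI2} and 28 streams.
    """
    config.validate()
    out = Path(out_dir)
    try:
        (out / "streams").mkdir(parents=True, exist_ok=True)
        (out / "logs").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    baselines = config.resolved_baseline_mu()
    manifest_rows = []
    truth_rows = []
    interval_frames = []
    for p in range(1, config.n_participants + 1):
        for dep in config.deployment_plan[p - 1]:
            for k in range(config.evas_per_deployment):
                stream, true_log, jittered_log = generate_eva(config, p, dep, k)
                name = f"p{p}_{dep}_eva{k}"
                stream_path = f"streams/{name}.csv"
                log_path = f"logs/{name}.csv"
                stream.to_csv(out / stream_path, index=False, float_format="%.1f")
                jittered_log.to_csv(out / log_path, index=False)
                manifest_rows.append(
                    {
                        "participant": p,
                        "deployment": dep,
                        "eva": k,
                        "stream_path": stream_path,
                        "log_path": log_path,
                        "clock_offset_s": 0,
                    }
                )
                tl = true_log.copy()
                tl.insert(0, "eva", k)
                tl.insert(0, "deployment", dep)
                tl.insert(0, "participant", p)
                interval_frames.append(tl)
            for param in PARAMETERS:
                for task in TASK_CODES:
                    truth_rows.append(
                        {
                            "participant": p,
                            "deployment": dep,
                            "parameter": param,
                            "task_code": task,
                            "true_mean": baselines[param][p - 1]
                            + (config.deployment_shift or {}).get(dep, {}).get(param, 0.0)
                            + config.task_effect.get(task, {}).get(param, 0.0),
                        }
                    )

    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    truth = GroundTruth(
        true_means=pd.DataFrame(truth_rows),
        intervals=pd.concat(interval_frames, ignore_index=True),
    )
    logger.info("campaign written to %s: %d streams", out, len(manifest))
    return manifest, truth


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for determinism checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
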