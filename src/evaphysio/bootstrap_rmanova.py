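"""Non-parametric bootstrap one-way ANOVA over task levels, per case.

The occurrence means within one case form a one-way layout with up to six
task levels (baseline plus five field tasks).  Because the underlying data
are not assumed normal, no parametric F-test or p-values are produced.
Instead, case resampling stratified by task — every replicate redraws each
task stratum with replacement at its original size, so each replicate has
the same number of data points as the original — yields a bootstrap
distribution of every pairwise difference of level means (the least-square
difference, LSD, of a one-way layout).  An equal-tailed percentile interval
at a conservative confidence level (default 99.98%, chosen to offset the
family error across many comparisons) is attached to each pair, and the
difference is declared significant exactly when zero falls outside the
interval.

The sign convention is mean(task_a) − mean(task_b): a ``Base-BR`` row holds
the mean baseline response minus the mean breaking-rocks response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CONTRASTS, PARAMETERS, contrast_label

logger = logging.getLogger(__name__)

PAIRWISE_COLUMNS = [
    "case_id",
    "parameter",
    "contrast",
    "task_a",
    "task_b",
    "lsd",
    "ci_low",
    "ci_high",
    "significant",
    "n_a",
    "n_b",
]

# cap on elements drawn per chunk, to bound peak memory during resampling
_MAX_CHUNK_ELEMS = 1 << 24


@dataclass
class BootstrapSpec:
    """Resampling plan: replicate count, confidence level, seed, scheme.

    The default 100,000 replicates leave >= 10 order statistics in each
    0.01% tail of a 99.98% interval.  Far fewer replicates than the tail
    mass can resolve make the percentile endpoints rest on interpolation
    toward the extremes — legal, increasingly conservative, and warned
    about.
    """

    n_replicates: int = 100_000
    ci_level: float = 99.98
    seed: int | None = 0
    resampling_scheme: str = "stratified-by-task"

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 100.0):
            raise ValueError(f"ci_level must lie in (0, 100), got {self.ci_level}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.resampling_scheme not in ("stratified-by-task", "pooled"):
            raise ValueError(f"unknown resampling_scheme {self.resampling_scheme!r}")
        per_tail = self.n_replicates * (100.0 - self.ci_level) / 200.0
        if per_tail < 10.0:
            warnings.warn(
                f"{self.n_replicates} replicates leave only ~{per_tail:.1f} order "
                f"statistics per tail of a {self.ci_level}% interval; endpoints "
                "will interpolate toward the sample extremes (conservative)",
                stacklevel=2,
            )

    @property
    def tail_percentiles(self) -> tuple[float, float]:
        half = (100.0 - self.ci_level) / 2.0
        return half, 100.0 - half


@dataclass(frozen=True)
class PairwiseResult:
    """LSD estimate, percentile CI and significance for one task pair."""

    case_id: int
    parameter: str
    task_a: str
    task_b: str
    lsd: float
    ci_low: float
    ci_high: float
    significant: bool
    n_a: int
    n_b: int

    @property
    def contrast(self) -> str:
        return contrast_label(self.task_a, self.task_b)


def observed_lsd(case_means: pd.DataFrame, task_a: str, task_b: str) -> float:
    """Unweighted difference of task-level means of the occurrence means,
    mean(task_a) − mean(task_b).  NaN if either task was not performed."""
    a = case_means.loc[case_means["task_code"] == task_a, "mean_value"]
    b = case_means.loc[case_means["task_code"] == task_b, "mean_value"]
    if a.empty or b.empty:
        return float("nan")
    return float(a.mean() - b.mean())


def bootstrap_replicate(
    strata: Mapping[str, np.ndarray], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One stratified case resample: each task stratum redrawn with
    replacement at its own size, so the replicate has exactly the original
    per-task counts."""
    return {
        task: np.asarray(v)[rng.integers(0, len(v), size=len(v))]
        for task, v in strata.items()
    }


def replicate_level_means(
    strata_values: Sequence[np.ndarray],
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized stratified resampling: (n_replicates, k) matrix of
    per-replicate task-level means."""
    out = np.empty((n_replicates, len(strata_values)))
    for j, v in enumerate(strata_values):
        v = np.asarray(v, dtype=float)
        n = v.size
        chunk = max(1, min(n_replicates, _MAX_CHUNK_ELEMS // max(n, 1)))
        for start in range(0, n_replicates, chunk):
            stop = min(start + chunk, n_replicates)
            idx = rng.integers(0, n, size=(stop - start, n))
            out[start:stop, j] = v[idx].mean(axis=1)
    return out


def _pooled_level_means(
    strata_values: Sequence[np.ndarray],
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sensitivity variant: resample the pooled case ignoring task strata;
    per-task counts then vary and a task may vanish from a replicate (NaN
    level mean)."""
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in strata_values])
    labels = np.concatenate(
        [np.full(len(v), j) for j, v in enumerate(strata_values)]
    )
    n_total = pooled.size
    k = len(strata_values)
    out = np.empty((n_replicates, k))
    chunk = max(1, min(n_replicates, _MAX_CHUNK_ELEMS // n_total))
    for start in range(0, n_replicates, chunk):
        stop = min(start + chunk, n_replicates)
        idx = rng.integers(0, n_total, size=(stop - start, n_total))
        vals = pooled[idx]
        labs = labels[idx]
        for j in range(k):
            mask = labs == j
            cnt = mask.sum(axis=1)
            with np.errstate(invalid="ignore"):
                out[start:stop, j] = np.where(
                    cnt > 0, (vals * mask).sum(axis=1) / cnt, np.nan
                )
    return out


def pairwise_from_strata(
    strata: Mapping[str, np.ndarray],
    spec: BootstrapSpec,
    rng: np.random.Generator | None = None,
    case_id: int = 0,
    parameter: str = "",
) -> list[PairwiseResult]:
    """Bootstrap pairwise CIs for every ordered-canonical task pair among
    the present (non-empty) strata.

    This is the numerical core; :func:`pairwise_ci` wraps it in the tabular
    interface.  Strata with zero occurrences are excluded with a notice;
    with fewer than two non-empty strata an empty list is returned.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    present = {t: np.asarray(v, dtype=float) for t, v in strata.items() if len(v) > 0}
    dropped = set(strata) - set(present)
    if dropped:
        logger.info("excluding task level(s) with no occurrences: %s", sorted(dropped))
    if len(present) < 2:
        logger.info("case %s/%s has < 2 task levels; skipped", case_id, parameter)
        return []
    tasks = list(present)
    values = [present[t] for t in tasks]
    if spec.resampling_scheme == "stratified-by-task":
        level_means = replicate_level_means(values, spec.n_replicates, rng)
    else:
        level_means = _pooled_level_means(values, spec.n_replicates, rng)
    observed = {t: float(v.mean()) for t, v in present.items()}
    lo_pct, hi_pct = spec.tail_percentiles
    results = []
    for task_a, task_b in CONTRASTS:
        if task_a not in present or task_b not in present:
            continue
        ia, ib = tasks.index(task_a), tasks.index(task_b)
        diffs = level_means[:, ia] - level_means[:, ib]
        if np.isnan(diffs).any():  # pooled scheme: task absent from some replicates
            lo, hi = np.nanpercentile(diffs, [lo_pct, hi_pct])
        else:
            lo, hi = np.percentile(diffs, [lo_pct, hi_pct])
        lsd = observed[task_a] - observed[task_b]
        results.append(
            PairwiseResult(
                case_id=case_id,
                parameter=parameter,
                task_a=task_a,
                task_b=task_b,
                lsd=lsd,
                ci_low=float(lo),
                ci_high=float(hi),
                significant=bool(lo > 0.0 or hi < 0.0),
                n_a=int(present[task_a].size),
                n_b=int(present[task_b].size),
            )
        )
    return results


def _results_to_frame(
    results: list[PairwiseResult], case_id: int, parameter: str
) -> pd.DataFrame:
    """All 15 canonical contrast rows; contrasts with an unperformed task
    appear with NaN estimate and zero counts (the blank-cell convention)."""
    by_pair = {(r.task_a, r.task_b): r for r in results}
    counts = {r.task_a: r.n_a for r in results} | {r.task_b: r.n_b for r in results}
    rows = []
    for task_a, task_b in CONTRASTS:
        r = by_pair.get((task_a, task_b))
        rows.append(
            {
                "case_id": case_id,
                "parameter": parameter,
                "contrast": contrast_label(task_a, task_b),
                "task_a": task_a,
                "task_b": task_b,
                "lsd": r.lsd if r else np.nan,
                "ci_low": r.ci_low if r else np.nan,
                "ci_high": r.ci_high if r else np.nan,
                "significant": r.significant if r else False,
                "n_a": r.n_a if r else counts.get(task_a, 0),
                "n_b": r.n_b if r else counts.get(task_b, 0),
            }
        )
    return pd.DataFrame(rows, columns=PAIRWISE_COLUMNS)


def pairwise_ci(
    case_means: pd.DataFrame,
    spec: BootstrapSpec,
    case_id: int = 0,
    parameter: str = "",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pairwise bootstrap table for one case's occurrence means.

    ``case_means`` needs columns ``task_code`` and ``mean_value``.  Emits
    all 15 canonical contrasts; pairs involving a task the participant never
    performed carry NaN estimates and are never significant.  Returns an
    empty frame (with a notice) when fewer than two task levels are present.
    """
    strata = {
        t: g["mean_value"].to_numpy() for t, g in case_means.groupby("task_code", sort=False)
    }
    results = pairwise_from_strata(strata, spec, rng=rng, case_id=case_id, parameter=parameter)
    if not results:
        return pd.DataFrame(columns=PAIRWISE_COLUMNS)
    return _results_to_frame(results, case_id, parameter)


def pairwise_all(
    means: pd.DataFrame, cases: pd.DataFrame, spec: BootstrapSpec
) -> pd.DataFrame:
    """Run the bootstrap over every case in a cases table.

    Each case gets an independent RNG derived from (spec.seed, parameter
    index, case id), so results do not depend on iteration order.
    """
    frames = []
    base_seed = 0 if spec.seed is None else int(spec.seed)
    for row in cases.itertuples(index=False):
        deps = row.deployments.split("/")
        sub = means[
            (means["participant"] == row.participant)
            & (means["parameter"] == row.parameter)
            & (means["deployment"].isin(deps))
        ]
        rng = np.random.default_rng(
            [base_seed, PARAMETERS.index(row.parameter), int(row.case_id)]
        )
        frames.append(
            pairwise_ci(sub, spec, case_id=int(row.case_id), parameter=row.parameter, rng=rng)
        )
    if not frames:
        return pd.DataFrame(columns=PAIRWISE_COLUMNS)
    return pd.concat(frames, ignore_index=True)
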