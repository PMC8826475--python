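"""Collapse each contiguous task occurrence into one mean per parameter.

1 Hz samples within a task episode are heavily autocorrelated, so the unit
of analysis is the occurrence mean: every maximal run of consecutive
surviving seconds sharing a task label within one EVA yields one mean per
physiological parameter.  Gaps created purely by the confidence filter do
not split an occurrence — the occurrence is defined by the task episode,
not by data continuity — but any change of label does, and occurrences
never span EVAs or deployments.

HRV needs a minimum number of valid readings before a within-occurrence
value is meaningful, so short occurrences are emitted for HR/RR but
suppressed for HRV (default minimum: 60 valid samples, one minute at 1 Hz).
"""

from __future__ import annotations

import logging

import pandas as pd

from .constants import PARAMETER_COLUMNS

logger = logging.getLogger(__name__)

#: Minimum valid HRV samples for an occurrence to yield an HRV mean.
DEFAULT_HRV_MIN_SAMPLES = 60

MEANS_COLUMNS = [
    "participant",
    "deployment",
    "eva",
    "task_code",
    "occurrence_index",
    "parameter",
    "mean_value",
    "n_samples",
]

_GROUP = ["participant", "deployment", "eva"]


def segment_occurrences(labeled: pd.DataFrame) -> pd.DataFrame:
    """Assign each labeled record an ``occurrence_index``: the ordinal of
    its maximal same-label run within its (participant, deployment, eva).

    Records must be sorted by time within each EVA.  A label change always
    starts a new occurrence; time gaps between same-label records (from the
    confidence filter) do not.
    """
    if labeled.empty:
        out = labeled.copy()
        out["occurrence_index"] = pd.Series(dtype=int)
        return out
    out = labeled.copy()
    grp = out.groupby(_GROUP, sort=False)
    new_run = (out["task_code"] != grp["task_code"].shift()).fillna(True)
    out["occurrence_index"] = new_run.groupby(
        [out[c] for c in _GROUP], sort=False
    ).cumsum().astype(int)
    return out


def occurrence_means(
    segmented: pd.DataFrame, hrv_min_samples: int = DEFAULT_HRV_MIN_SAMPLES
) -> pd.DataFrame:
    """One arithmetic mean per occurrence per parameter, over non-missing
    values.  Occurrences with zero valid values for a parameter — and HRV
    occurrences with fewer than ``hrv_min_samples`` valid values — are
    suppressed (with a logged count), not errors.
    """
    if segmented.empty:
        return pd.DataFrame(columns=MEANS_COLUMNS)
    keys = _GROUP + ["task_code", "occurrence_index"]
    frames = []
    for param, col in PARAMETER_COLUMNS.items():
        agg = (
            segmented.groupby(keys, sort=False)[col]
            .agg(mean_value="mean", n_samples="count")
            .reset_index()
        )
        min_n = hrv_min_samples if param == "HRV" else 1
        ok = agg["n_samples"] >= min_n
        if (~ok).any():
            logger.info(
                "%s: suppressed %d occurrence(s) with < %d valid samples",
                param,
                int((~ok).sum()),
                min_n,
            )
        agg = agg[ok].copy()
        agg.insert(len(keys), "parameter", param)
        frames.append(agg)
    out = pd.concat(frames, ignore_index=True)
    return out[MEANS_COLUMNS]


def aggregate(
    labeled: pd.DataFrame, hrv_min_samples: int = DEFAULT_HRV_MIN_SAMPLES
) -> pd.DataFrame:
    """Convenience composition: segment then take occurrence means."""
    return occurrence_means(segment_occurrences(labeled), hrv_min_samples)
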