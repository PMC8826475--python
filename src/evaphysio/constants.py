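"""Shared vocabulary: task codes, deployment codes, parameters, contrast order.

Task codes follow the EVA task taxonomy: five field tasks plus a baseline
rest condition.  Deployments are the three field campaigns (Idaho 2016,
Hawai'i 2016, Hawai'i 2017).  The canonical contrast order matches the
pairwise-difference tables of the analysis (Base first, then alphabetical).
"""

from __future__ import annotations

from itertools import combinations

#: Baseline rest condition.
BASE = "Base"

#: Field task codes: translation, observation, instrument use, breaking
#: rocks, bagging samples / biological sterilization.
FIELD_TASKS: tuple[str, ...] = ("ET", "EO", "EI", "BR", "BS")

#: All task codes, baseline included.
TASK_CODES: tuple[str, ...] = (BASE,) + FIELD_TASKS

#: Physically strenuous tasks, used for the carry-over model.
STRENUOUS_TASKS: tuple[str, ...] = ("ET", "BR")

#: Deployment codes in canonical (chronological) order.
DEPLOYMENTS: tuple[str, ...] = ("ID", "HI1", "HI2")

#: Physiological parameters: heart rate (bpm), respiration rate
#: (breaths/min), heart rate variability (ms).
PARAMETERS: tuple[str, ...] = ("HR", "RR", "HRV")

#: Column of the labeled stream holding each parameter.
PARAMETER_COLUMNS: dict[str, str] = {
    "HR": "hr_bpm",
    "RR": "rr_brpm",
    "HRV": "hrv_ms",
}

# Contrast order used in the pairwise output tables: tasks sorted
# Base, BR, BS, EI, EO, ET; all 15 unordered pairs in lexicographic order.
_CONTRAST_TASK_ORDER: tuple[str, ...] = ("Base", "BR", "BS", "EI", "EO", "ET")

#: The 15 canonical task contrasts, e.g. ("Base", "BR") rendered "Base-BR".
CONTRASTS: tuple[tuple[str, str], ...] = tuple(combinations(_CONTRAST_TASK_ORDER, 2))


def contrast_label(task_a: str, task_b: str) -> str:
    """Render a contrast as ``"Base-BR"``; the difference is mean(a) - mean(b)."""
    return f"{task_a}-{task_b}"


def deployment_sort_key(code: str) -> int:
    """Canonical ordering ID < HI1 < HI2 used for deterministic tie-breaks."""
    return DEPLOYMENTS.index(code)
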