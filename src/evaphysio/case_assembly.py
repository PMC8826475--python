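"""Decide which deployments' data may be pooled into one analysis "case".

A participant who took part in more than one field deployment may — or may
not — show the same response distribution in each.  Per participant and
physiological parameter, two-sample Kolmogorov–Smirnov tests compare the
pooled occurrence means of each pair of deployments; deployments whose
distributions are not distinguishable are combined into a single case to
increase the number of data points, otherwise they are analysed separately.
With two deployments a single comparison is made at alpha 0.05; with three
deployments the three pairwise comparisons each use alpha 0.017 to offset
the family error rate.

KS outcomes need not be transitive (A~B, B~C, A≁C).  Cases are therefore
the maximal cliques of the non-significance graph, assigned greedily by
descending pooled sample size with a deterministic ID < HI1 < HI2
tie-break; deployments left over become singleton cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .constants import DEPLOYMENTS, PARAMETERS, deployment_sort_key
from .errors import DataError

logger = logging.getLogger(__name__)

ALPHA_TWO_DEFAULT = 0.05
ALPHA_THREE_DEFAULT = 0.017
FAMILY_ALPHA_DEFAULT = 0.05

CASES_COLUMNS = ["case_id", "participant", "parameter", "deployments", "n_means"]


@dataclass(frozen=True)
class CaseDefinition:
    """One participant × parameter grouping of deployments pooled for
    inference."""

    case_id: int
    participant: int
    parameter: str
    deployments: tuple[str, ...]
    n_means: int

    @property
    def label(self) -> str:
        return "/".join(self.deployments)


def ks_two_sample(x, y, method: str = "asymp") -> tuple[float, float]:
    """Two-sided two-sample KS test.

    Returns (D, p) where D is the supremum distance between the empirical
    CDFs.  ``method`` is ``"asymp"`` (asymptotic null distribution with the
    standard effective-sample-size correction) or ``"exact"``.  Symmetric in
    its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("KS test requires non-empty samples")
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def select_alpha(
    n_deployments: int,
    alpha_two: float = ALPHA_TWO_DEFAULT,
    alpha_three: float = ALPHA_THREE_DEFAULT,
    family_alpha: float = FAMILY_ALPHA_DEFAULT,
) -> float | None:
    """Per-comparison alpha for the pooling decision.

    One deployment needs no test (returns None).  Two deployments: a single
    comparison at ``alpha_two``.  Three: each of the three pairwise
    comparisons at ``alpha_three``.  More than three (not part of the study
    design) generalizes to ``family_alpha / C(n, 2)``.
    """
    if n_deployments < 1:
        raise ValueError("n_deployments must be >= 1")
    if n_deployments == 1:
        return None
    if n_deployments == 2:
        return alpha_two
    if n_deployments == 3:
        return alpha_three
    alpha = family_alpha / comb(n_deployments, 2)
    logger.info("using Bonferroni alpha %.5f for %d deployments", alpha, n_deployments)
    return alpha


def build_cases(
    means: pd.DataFrame,
    participant: int,
    parameter: str,
    alpha_two: float = ALPHA_TWO_DEFAULT,
    alpha_three: float = ALPHA_THREE_DEFAULT,
    method: str = "asymp",
) -> list[CaseDefinition]:
    """Partition one participant's deployments into cases for one parameter.

    All of the participant's occurrence means for the parameter (all tasks,
    baseline included) are pooled per deployment; each deployment pair is
    compared by KS at the alpha selected for the number of deployments, an
    edge joins non-significant pairs, and maximal cliques are assigned
    greedily by descending combined n (ID < HI1 < HI2 tie-break).
    ``case_id`` is 0 here; :func:`assemble_cases` numbers cases globally.
    """
    sub = means[(means["participant"] == participant) & (means["parameter"] == parameter)]
    deps = sorted(sub["deployment"].unique(), key=deployment_sort_key)
    if not deps:
        return []
    samples = {d: sub.loc[sub["deployment"] == d, "mean_value"].to_numpy() for d in deps}
    alpha = select_alpha(len(deps), alpha_two, alpha_three)
    g = nx.Graph()
    g.add_nodes_from(deps)
    if alpha is not None:
        for i, a in enumerate(deps):
            for b in deps[i + 1 :]:
                _, p = ks_two_sample(samples[a], samples[b], method=method)
                if p > alpha:
                    g.add_edge(a, b)
    cliques = [tuple(sorted(c, key=deployment_sort_key)) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-sum(samples[d].size for d in c),
                                tuple(deployment_sort_key(d) for d in c)))
    assigned: set[str] = set()
    groups: list[tuple[str, ...]] = []
    for clique in cliques:
        if assigned.isdisjoint(clique):
            groups.append(clique)
            assigned.update(clique)
    for d in deps:  # anything not covered becomes a singleton
        if d not in assigned:
            groups.append((d,))
            assigned.add(d)
    groups.sort(key=lambda c: deployment_sort_key(c[0]))
    return [
        CaseDefinition(
            case_id=0,
            participant=participant,
            parameter=parameter,
            deployments=grp,
            n_means=int(sum(samples[d].size for d in grp)),
        )
        for grp in groups
    ]


def assemble_cases(
    means: pd.DataFrame,
    alpha_two: float = ALPHA_TWO_DEFAULT,
    alpha_three: float = ALPHA_THREE_DEFAULT,
    method: str = "asymp",
) -> pd.DataFrame:
    """Build the full cases table over every participant and parameter.

    Cases are numbered 1..K independently per parameter, ordered by
    participant then by deployment order, mirroring the per-parameter case
    tables of the analysis.  Columns: ``case_id, participant, parameter,
    deployments`` (slash-joined), ``n_means``.
    """
    rows = []
    for parameter in PARAMETERS:
        sub = means[means["parameter"] == parameter]
        case_id = 0
        for participant in sorted(sub["participant"].unique()):
            for case in build_cases(
                means, participant, parameter, alpha_two, alpha_three, method
            ):
                case_id += 1
                rows.append(
                    {
                        "case_id": case_id,
                        "participant": participant,
                        "parameter": parameter,
                        "deployments": case.label,
                        "n_means": case.n_means,
                    }
                )
    return pd.DataFrame(rows, columns=CASES_COLUMNS)


def case_deployments(cases_row) -> tuple[str, ...]:
    """Parse the slash-joined deployments field back into codes."""
    deps = tuple(cases_row["deployments"].split("/"))
    for d in deps:
        if d not in DEPLOYMENTS:
            raise DataError(f"unknown deployment code in cases table: {d!r}")
    return deps
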