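"""Summary surfaces: significance-count matrices, family-wise error
arithmetic, and per-case mean-response tables.

The significance summary counts, per contrast and parameter, how many cases
showed a significant pairwise difference out of the cases in which both
tasks were actually performed (denominators vary because one participant
may never perform a task).  Percentages are reported round-half-up to the
nearest integer alongside the exact counts.  The family-wise error rate of
a table of m comparisons each at per-comparison level alpha is
1 − (1 − alpha)^m under independence.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .constants import CONTRASTS, PARAMETERS, TASK_CODES, contrast_label

SUMMARY_COLUMNS = (
    ["contrast"]
    + [f"{p}_{s}" for p in PARAMETERS for s in ("k", "n", "pct")]
    + ["total_k", "total_n", "total_pct"]
)

MEAN_RESPONSE_COLUMNS = [
    "parameter",
    "case_id",
    "participant",
    "task_code",
    "mean_response",
    "n_occurrences",
]


def percent(k: int, n: int) -> float:
    """Round-half-up integer percentage of k/n; NaN when n == 0."""
    if n == 0:
        return float("nan")
    return float(math.floor(100.0 * k / n + 0.5))


def family_error(per_comparison_alpha: float, n_comparisons: int) -> float:
    """FWER under independence: 1 − (1 − alpha)^n."""
    if not (0.0 < per_comparison_alpha < 1.0):
        raise ValueError("per_comparison_alpha must lie in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return 1.0 - (1.0 - per_comparison_alpha) ** n_comparisons


def summarize_significance(pairs: pd.DataFrame) -> pd.DataFrame:
    """Contrast × parameter significance counts with row and grand totals.

    A case enters a contrast's denominator only if both tasks were
    performed there (``n_a > 0`` and ``n_b > 0``).  The final row "Total"
    sums each parameter column; the ``total_*`` columns sum across
    parameters.
    """
    if pairs.empty:
        pairs = pd.DataFrame(
            columns=["parameter", "contrast", "significant", "n_a", "n_b"]
        )
    rows = []
    for task_a, task_b in CONTRASTS:
        label = contrast_label(task_a, task_b)
        row: dict[str, object] = {"contrast": label}
        tot_k = tot_n = 0
        for param in PARAMETERS:
            sub = pairs[(pairs["parameter"] == param) & (pairs["contrast"] == label)]
            performed = sub[(sub["n_a"] > 0) & (sub["n_b"] > 0)]
            k = int(performed["significant"].sum())
            n = int(len(performed))
            row[f"{param}_k"], row[f"{param}_n"], row[f"{param}_pct"] = k, n, percent(k, n)
            tot_k += k
            tot_n += n
        row["total_k"], row["total_n"], row["total_pct"] = tot_k, tot_n, percent(tot_k, tot_n)
        rows.append(row)
    total: dict[str, object] = {"contrast": "Total"}
    for param in PARAMETERS:
        k = sum(int(r[f"{param}_k"]) for r in rows)
        n = sum(int(r[f"{param}_n"]) for r in rows)
        total[f"{param}_k"], total[f"{param}_n"], total[f"{param}_pct"] = k, n, percent(k, n)
    k = sum(int(r["total_k"]) for r in rows)
    n = sum(int(r["total_n"]) for r in rows)
    total["total_k"], total["total_n"], total["total_pct"] = k, n, percent(k, n)
    rows.append(total)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def mean_response_table(means: pd.DataFrame, cases: pd.DataFrame) -> pd.DataFrame:
    """Per-case, per-task grand mean of occurrence means and occurrence
    count — the numeric content of the per-case response bar charts.  A
    task never performed in a case keeps its row with a NaN mean and zero
    count (explicit gap, no imputation)."""
    rows = []
    for case in cases.itertuples(index=False):
        deps = case.deployments.split("/")
        sub = means[
            (means["participant"] == case.participant)
            & (means["parameter"] == case.parameter)
            & (means["deployment"].isin(deps))
        ]
        for task in TASK_CODES:
            vals = sub.loc[sub["task_code"] == task, "mean_value"]
            rows.append(
                {
                    "parameter": case.parameter,
                    "case_id": case.case_id,
                    "participant": case.participant,
                    "task_code": task,
                    "mean_response": float(vals.mean()) if len(vals) else np.nan,
                    "n_occurrences": int(len(vals)),
                }
            )
    return pd.DataFrame(rows, columns=MEAN_RESPONSE_COLUMNS)


def plot_mean_responses(mean_responses: pd.DataFrame, out_path) -> None:
    """Optional rendering of the mean-response table as grouped bar charts,
    one panel per case, one figure per parameter (written as
    ``<out_path>/mean_responses_<param>.png``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_path)
    out.mkdir(parents=True, exist_ok=True)
    for param, sub in mean_responses.groupby("parameter"):
        case_ids = sorted(sub["case_id"].unique())
        ncols = min(5, len(case_ids))
        nrows = -(-len(case_ids) // ncols)
        fig, axes = plt.subplots(
            nrows, ncols, figsize=(3 * ncols, 2.5 * nrows), squeeze=False
        )
        for ax, cid in zip(axes.flat, case_ids):
            c = sub[sub["case_id"] == cid].set_index("task_code")
            c = c.reindex(list(TASK_CODES))
            ax.bar(c.index, c["mean_response"])
            ax.set_title(f"Case {cid}")
            ax.tick_params(axis="x", labelsize=7)
        for ax in axes.flat[len(case_ids):]:
            ax.axis("off")
        fig.suptitle(f"Mean {param} response by task")
        fig.tight_layout()
        fig.savefig(out / f"mean_responses_{param}.png", dpi=100)
        plt.close(fig)
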