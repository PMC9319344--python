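"""Rank-sum screening of hub genes in biofluid and therapy-response cohorts.

Each candidate gene is tested case-vs-control (urine, blood plasma) or
between ordinal chemotherapy-response groups (no / partial / complete, plus
the pooled no-vs-any-response contrast) with the two-sided Wilcoxon rank-sum
test: exact when the smaller group has at most 8 observations and there are
no ties, normal approximation with tie and continuity correction otherwise.
No across-gene multiplicity correction is applied — the screen deliberately
filters at raw p < 0.05, which is faithful to common hub-screen practice but
liberal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

RESPONSE_ORDER = ("no", "partial", "complete")


@dataclass
class FluidScreenResult:
    gene: str
    statistic: float
    p: float
    significant: bool
    cohort_id: str
    comparison: str
    direction: str  # "up" (higher in first group) or "down"


def _rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(np.unique(np.r_[x, y])) == 1:
        warnings.warn("all values tied within and across groups; p = 1",
                      stacklevel=3)
        return float(len(x) * len(y) / 2.0), 1.0
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_screen(
    case_matrix: pd.DataFrame,
    control_matrix: pd.DataFrame,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    cohort_id: str = "cohort",
    comparison: str = "case_vs_control",
) -> list[FluidScreenResult]:
    """Per-gene two-sided rank-sum test between case and control samples.

    Matrices are samples × genes; requires at least 2 samples per group.
    """
    if len(case_matrix) < 2 or len(control_matrix) < 2:
        raise ValueError("need at least 2 samples per group")
    if genes is None:
        genes = [g for g in case_matrix.columns if g in set(control_matrix.columns)]
    out = []
    for g in genes:
        x = case_matrix[g].to_numpy(dtype=float)
        y = control_matrix[g].to_numpy(dtype=float)
        stat, p = _rank_sum(x, y)
        out.append(
            FluidScreenResult(
                gene=g,
                statistic=stat,
                p=p,
                significant=p < alpha,
                cohort_id=cohort_id,
                comparison=comparison,
                direction="up" if np.median(x) >= np.median(y) else "down",
            )
        )
    return out


def screen_table(results: list[FluidScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.cohort_id, r.comparison, r.gene, r.statistic, r.p, r.significant,
             r.direction)
            for r in results
        ],
        columns=["cohort", "comparison", "gene", "W", "p", "significant",
                 "direction"],
    )


def response_group_tests(
    expr: pd.DataFrame,
    response_labels: pd.Series,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    cohort_id: str = "response",
) -> list[FluidScreenResult]:
    """Rank-sum tests across ordinal response groups.

    Emits the three pairwise contrasts (no-vs-partial, no-vs-complete,
    partial-vs-complete) and the pooled no-vs-(partial+complete) contrast;
    a contrast with an empty group is skipped with a warning.
    """
    labels = response_labels.loc[expr.index]
    bad = set(labels.unique()) - set(RESPONSE_ORDER)
    if bad:
        raise ValueError(f"unknown response labels: {bad}")
    groups = {lv: expr.loc[labels == lv] for lv in RESPONSE_ORDER}
    contrasts: list[tuple[str, pd.DataFrame, pd.DataFrame]] = []
    for a, b in combinations(RESPONSE_ORDER, 2):
        contrasts.append((f"{a}_vs_{b}", groups[a], groups[b]))
    pooled = pd.concat([groups["partial"], groups["complete"]])
    contrasts.append(("no_vs_any_response", groups["no"], pooled))

    out: list[FluidScreenResult] = []
    for name, ga, gb in contrasts:
        if len(ga) < 2 or len(gb) < 2:
            warnings.warn(f"comparison {name} skipped (empty or tiny group)",
                          stacklevel=2)
            continue
        out.extend(
            wilcoxon_screen(ga, gb, genes=genes, alpha=alpha,
                            cohort_id=cohort_id, comparison=name)
        )
    return out
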