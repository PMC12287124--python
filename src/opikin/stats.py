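"""Two-cohort comparison of per-case OPI values with a normality gate.

For each (step, metric) cell the two groups are compared with Student's
independent t test when both groups pass a Shapiro-Wilk normality check
(alpha = 0.05 per group), and with the two-sided Mann-Whitney U test
otherwise.  Parametric cells are summarized as mean (95% CI, t distribution
with n-1 df); nonparametric cells as median [IQR].  p < 0.05 is flagged as
significant and no multiple-testing correction is applied by default (a
Benjamini-Hochberg mode is available but off).

The unit of analysis is the case: one value per case per group per (step,
metric), averaging within a case if several same-group operators contributed
to the step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .ontology import STEP_INDEX, Step
from .opi import StepOPI

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: metrics compared by default, in reporting order
DEFAULT_METRICS: Tuple[str, ...] = (
    "total_task_duration_s",
    "pct_active_console",
    "pct_active_dom",
    "pct_active_nondom",
    "speed_dom_cm_s",
    "speed_nondom_cm_s",
    "bimanual_dexterity",
    "workspace_rate_cm3_s",
    "workspace_per_pathlength_cm2",
)


class InsufficientDataError(ValueError):
    """A group has too few non-missing values to be compared."""


@dataclass
class GroupSummary:
    group_label: str
    n: int
    mean: float
    ci_low: float
    ci_high: float
    median: float
    q1: float
    q3: float


@dataclass
class ComparisonRow:
    """One step x metric two-group comparison."""

    step: Optional[Step]
    metric: Optional[str]
    summary_a: GroupSummary
    summary_b: GroupSummary
    test_used: str  # "t_test" | "mann_whitney"
    p_value: float
    significant: bool
    degenerate: bool = False


def summarize(values: Sequence[float], label: str) -> GroupSummary:
    """Parametric and nonparametric summaries of one group."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    mean = float(x.mean())
    if n > 1 and x.std(ddof=1) > 0:
        half = float(sps.t.ppf(0.975, n - 1) * x.std(ddof=1) / math.sqrt(n))
    else:
        half = 0.0
    q1, med, q3 = (float(v) for v in np.percentile(x, [25, 50, 75]))
    return GroupSummary(
        group_label=label, n=n, mean=mean, ci_low=mean - half, ci_high=mean + half,
        median=med, q1=q1, q3=q3,
    )


def normality_gate(values_a: Sequence[float], values_b: Sequence[float], alpha: float = ALPHA) -> bool:
    """True when both groups look normal (Shapiro-Wilk p >= alpha in each).

    Zero-variance groups are treated as non-normal.  Requires >= 3 values per
    group (the Shapiro-Wilk minimum).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"normality gate needs >= 3 values per group, got {len(a)} and {len(b)}"
        )
    for x in (a, b):
        if np.ptp(x) == 0:
            return False
        if sps.shapiro(x).pvalue < alpha:
            return False
    return True


def _mannwhitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact when both groups have n <= 8 and there are no ties; otherwise the
    normal approximation with continuity and tie correction.
    """
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    if len(a) <= 8 and len(b) <= 8 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
    *,
    step: Optional[Step] = None,
    metric: Optional[str] = None,
    parametric: Optional[bool] = None,
    equal_var: bool = True,
    alpha: float = ALPHA,
) -> ComparisonRow:
    """Compare two groups of per-case values with the normality-gated procedure.

    ``parametric`` forces the test choice when given; otherwise the gate
    decides.  ``equal_var=False`` selects Welch's t test on the parametric
    path.  All-identical values across both groups yield p = 1.0 by
    convention, flagged ``degenerate``.
    """
    a = np.asarray([v for v in values_a if v is not None and np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in values_b if v is not None and np.isfinite(v)], dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError(
            f"comparison needs >= 3 values per group, got {len(a)} and {len(b)}"
        )
    sa = summarize(a, label_a)
    sb = summarize(b, label_b)
    if np.ptp(np.concatenate([a, b])) == 0:
        logger.warning("all values identical in both groups (%s/%s): p=1 by convention", step, metric)
        return ComparisonRow(step, metric, sa, sb, "mann_whitney", 1.0, False, degenerate=True)
    if parametric is None:
        parametric = normality_gate(a, b, alpha=alpha)
    if parametric:
        p = float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)
        test = "t_test"
    else:
        p = _mannwhitney_p(a, b)
        test = "mann_whitney"
    return ComparisonRow(step, metric, sa, sb, test, p, bool(p < alpha))


def _per_case_values(
    opis: Sequence[StepOPI], step: Step, metric: str, roles: Sequence[str]
) -> List[float]:
    """One value per case: mean over that case's operators with a role in ``roles``."""
    by_case: Dict[str, List[float]] = {}
    for o in opis:
        if o.step != step or o.role not in roles:
            continue
        v = getattr(o, metric)
        if v is None or not np.isfinite(v):
            continue
        by_case.setdefault(o.case_id, []).append(float(v))
    return [float(np.mean(vs)) for _, vs in sorted(by_case.items())]


def build_comparison_table(
    opis: Sequence[StepOPI],
    roles_a: Sequence[str],
    roles_b: Sequence[str],
    *,
    metrics: Sequence[str] = DEFAULT_METRICS,
    label_a: Optional[str] = None,
    label_b: Optional[str] = None,
    equal_var: bool = True,
    alpha: float = ALPHA,
    fdr: bool = False,
) -> List[ComparisonRow]:
    """One :class:`ComparisonRow` per (step, metric) with both groups populated.

    ``roles_a`` / ``roles_b`` partition operator roles into the two cohorts,
    e.g. ``["attending"]`` vs ``["resident", "fellow"]``.  Rows are ordered by
    ontology step index then metric order.  ``fdr=True`` applies a
    Benjamini-Hochberg adjustment to the table's p-values (off by default:
    raw per-cell p-values are the primary output).
    """
    roles_a = list(roles_a)
    roles_b = list(roles_b)
    if not roles_a or not roles_b:
        raise ValueError("both group role lists must be non-empty")
    if set(roles_a) & set(roles_b):
        raise ValueError("group role lists must be disjoint")
    la = label_a or "+".join(roles_a)
    lb = label_b or "+".join(roles_b)

    present = {o.step for o in opis}
    known_metrics = set()
    for m in metrics:
        if any(getattr(o, m, None) is not None for o in opis):
            known_metrics.add(m)
        else:
            logger.warning("metric %r absent from every OPI row; skipped", m)

    rows: List[ComparisonRow] = []
    for step in sorted(present, key=lambda s: STEP_INDEX[s]):
        for m in metrics:
            if m not in known_metrics:
                continue
            va = _per_case_values(opis, step, m, roles_a)
            vb = _per_case_values(opis, step, m, roles_b)
            if not va or not vb:
                continue
            try:
                rows.append(
                    compare_groups(
                        va, vb, la, lb, step=step, metric=m,
                        equal_var=equal_var, alpha=alpha,
                    )
                )
            except InsufficientDataError as exc:
                logger.info("skipping %s/%s: %s", step.value, m, exc)
    if fdr and rows:
        adj = sps.false_discovery_control([r.p_value for r in rows], method="bh")
        for r, p in zip(rows, adj):
            r.p_value = float(p)
            r.significant = bool(p < alpha)
    return rows
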