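"""Performance metrics, reliability-stratified reports, LODO summaries and
the screening-center replicate-variability analysis.

Four metrics are computed between observed and predicted ComboScores:

    RMSE = sqrt(mean((y_obs - y_pred)^2))
    R^2  = 1 - RMSE^2 / Var(y_obs)          (population variance)
    R_p  = Pearson correlation
    R_s  = Spearman rank correlation (average ranks for ties)

Population (divisor N) variance keeps the R^2 = 1 - RMSE^2/Var identity
exact.  With constant observations the correlation-based metrics are
undefined and reported as NaN with a flag; RMSE is always valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .models import Prediction
from .scoring import SingleAgentRecord


@dataclass
class MetricsReport:
    """RMSE / R^2 / R_p / R_s for one evaluation context."""

    n: int
    rmse: float
    r2: float
    r_p: float
    r_s: float
    context: dict = field(default_factory=dict)
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "rmse": self.rmse,
            "r2": self.r2,
            "r_p": self.r_p,
            "r_s": self.r_s,
            "degenerate": self.degenerate,
            **self.context,
        }


def compute_metrics(
    y_obs: np.ndarray, y_pred: np.ndarray, context: dict | None = None
) -> MetricsReport:
    """RMSE, R^2, Pearson and Spearman between observed and predicted."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape:
        raise ValueError("y_obs and y_pred must have equal length")
    n = len(y_obs)
    if n < 2:
        raise ValueError("metrics require at least 2 samples")
    rmse = float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))
    var_obs = float(np.var(y_obs))  # population variance
    degenerate = var_obs == 0 or np.ptp(y_pred) == 0
    if var_obs == 0:
        r2 = math.nan
    else:
        r2 = 1.0 - rmse**2 / var_obs
    if degenerate:
        r_p = r_s = math.nan
    else:
        r_p = float(stats.pearsonr(y_obs, y_pred).statistic)
        r_s = float(stats.spearmanr(y_obs, y_pred).statistic)
    return MetricsReport(
        n=n, rmse=rmse, r2=r2, r_p=r_p, r_s=r_s,
        context=context or {}, degenerate=bool(degenerate),
    )


def stratified_report(
    predictions: list[Prediction],
    y_obs: np.ndarray,
    strata: dict[str, np.ndarray],
    context: dict | None = None,
) -> dict[str, MetricsReport]:
    """Metrics on the most-reliable / all / least-reliable prediction strata."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.array([p.y_pred for p in predictions])
    out = {}
    for name in ("most_reliable", "all", "least_reliable"):
        idx = np.asarray(strata[name], dtype=int)
        ctx = {**(context or {}), "stratum": name}
        if len(idx) < 2:
            out[name] = MetricsReport(
                n=len(idx), rmse=math.nan, r2=math.nan, r_p=math.nan,
                r_s=math.nan, context=ctx, degenerate=True,
            )
            continue
        out[name] = compute_metrics(y_obs[idx], y_pred[idx], context=ctx)
    return out


def _quartiles(vals: np.ndarray) -> dict[str, float]:
    q = np.percentile(vals, [0, 25, 50, 75, 100])
    return {"min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4]}


def lodo_summary(reports: list[MetricsReport]) -> dict:
    """Summarize per-fold LODO metrics by cell line and by left-out drug.

    Each report's context must carry ``cell_line`` and ``left_out_drug``.
    Per cell line: quartile bands of fold R_p and median RMSE; per drug:
    median R_p and RMSE across cell lines.
    """
    by_cell: dict[str, list[MetricsReport]] = {}
    by_drug: dict[str, list[MetricsReport]] = {}
    for r in reports:
        by_cell.setdefault(r.context["cell_line"], []).append(r)
        by_drug.setdefault(r.context["left_out_drug"], []).append(r)
    per_cell = {
        cell: {
            "r_p": _quartiles(np.array([r.r_p for r in rs])),
            "rmse_median": float(np.median([r.rmse for r in rs])),
            "n_folds": len(rs),
        }
        for cell, rs in sorted(by_cell.items())
    }
    per_drug = {
        drug: {
            "r_p_median": float(np.median([r.r_p for r in rs])),
            "rmse_median": float(np.median([r.rmse for r in rs])),
            "n_cell_lines": len(rs),
        }
        for drug, rs in sorted(by_drug.items())
    }
    return {"per_cell_line": per_cell, "per_drug": per_drug}


@dataclass
class ReplicateSet:
    """Growth replicates of one (center, drug, concentration, cell line)
    across distinct test dates."""

    center: str
    drug: str
    conc: float
    cell_line: str
    growths: list[float]
    test_dates: list[str]

    @property
    def sd(self) -> float:
        return float(np.std(self.growths))  # population SD

    @property
    def singleton(self) -> bool:
        return len(self.growths) < 2


def replicate_variability(records: list[SingleAgentRecord]) -> dict:
    """Replicate SDs and testing intensity per screening center.

    Replicates are measurements of the same (center, drug, concentration,
    cell line) on distinct test dates (same-date duplicates are averaged
    first).  Reports the population SD per replicate set, the average
    number of distinct test dates per (drug, cell line) per center, and a
    paired table for (drug, concentration, cell line) sets matched across
    centers.
    """
    by_set: dict[tuple, dict[str, list[float]]] = {}
    for r in records:
        key = (r.center, r.drug, r.conc, r.cell_line)
        by_set.setdefault(key, {}).setdefault(r.test_date, []).append(r.growth)
    sets: list[ReplicateSet] = []
    for (center, drug, conc, cell), by_date in sorted(by_set.items()):
        dates = sorted(by_date)
        growths = [float(np.mean(by_date[d])) for d in dates]
        sets.append(ReplicateSet(center, drug, conc, cell, growths, dates))

    # average distinct test dates per (drug, cell line) per center
    dates_per_tuple: dict[str, list[int]] = {}
    seen: dict[tuple, set[str]] = {}
    for r in records:
        seen.setdefault((r.center, r.drug, r.cell_line), set()).add(r.test_date)
    for (center, _drug, _cell), dates in seen.items():
        dates_per_tuple.setdefault(center, []).append(len(dates))
    avg_tests = {
        c: float(np.mean(v)) for c, v in sorted(dates_per_tuple.items())
    }

    # paired comparison across centers for matched (drug, conc, cell) sets
    by_match: dict[tuple, dict[str, ReplicateSet]] = {}
    for s in sets:
        by_match.setdefault((s.drug, s.conc, s.cell_line), {})[s.center] = s
    paired = []
    for (drug, conc, cell), per_center in sorted(by_match.items()):
        if len(per_center) >= 2:
            paired.append(
                {
                    "drug": drug,
                    "conc": conc,
                    "cell_line": cell,
                    "sd_by_center": {c: s.sd for c, s in sorted(per_center.items())},
                }
            )
    return {
        "sets": sets,
        "avg_tests_per_drug_cell_line": avg_tests,
        "paired_sets": paired,
    }
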