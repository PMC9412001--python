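"""Noninferiority testing of pipeline-versus-expert performance.

With per-subject expert scores Y and pipeline scores X and a margin d,
the null hypothesis is that the pipeline is worse by more than the
margin, H0: E(Y − X) ≥ d, tested against H1: E(Y − X) < d with a
one-sided paired Student t-test on the shifted differences (Y − X − d):

    t = (mean(Y − X) − d) / (sd(Y − X) / sqrt(n)),   p = F_t(t; n − 1)

Rejecting H0 concludes the pipeline is noninferior: at most d worse,
possibly better. At d = 0 this is a standard one-sided paired t-test.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["NoninferiorityResult", "DegenerateDataError",
           "noninferiority_test", "compare_all"]


class DegenerateDataError(ValueError):
    pass


@dataclasses.dataclass
class NoninferiorityResult:
    margin: float
    differences: np.ndarray  # per-subject Y - X
    mean_difference: float
    t_statistic: float
    p_value: float
    n: int
    alpha: float
    reject_h0: bool

    def __repr__(self) -> str:  # compact scientific summary
        verdict = "noninferior" if self.reject_h0 else "not shown noninferior"
        return (f"NoninferiorityResult(mean Y-X={self.mean_difference:+.4f}, "
                f"d={self.margin}, t={self.t_statistic:.3f}, "
                f"p={self.p_value:.4g}, n={self.n}: {verdict})")


def noninferiority_test(expert_scores, pipeline_scores,
                        margin: float = 0.05,
                        alpha: float = 0.05) -> NoninferiorityResult:
    """One-sided paired t-test of H0: E(Y − X) ≥ margin."""
    y = np.asarray(expert_scores, dtype=float)
    x = np.asarray(pipeline_scores, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("expert and pipeline scores must be equal-length "
                         "1D sequences")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 paired subjects")
    diff = y - x
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError(
            "all per-subject differences are identical; the paired t-test "
            "is undefined (zero variance)")
    t = (diff.mean() - margin) / (sd / np.sqrt(n))
    p = float(sps.t.cdf(t, df=n - 1))
    return NoninferiorityResult(
        margin=margin, differences=diff, mean_difference=float(diff.mean()),
        t_statistic=float(t), p_value=p, n=n, alpha=alpha,
        reject_h0=p < alpha)


def compare_all(pipeline_scores: dict[str, dict[str, dict[str, np.ndarray]]],
                expert_scores: dict[str, dict[str, np.ndarray]],
                margin: float = 0.05, alpha: float = 0.05) -> pd.DataFrame:
    """Noninferiority table over every (pipeline, expert, metric) cell.

    ``pipeline_scores[pipeline][expert][metric]`` holds that pipeline's
    per-subject scores measured on the expert-specific (unbiased) ground
    truth; ``expert_scores[expert][metric]`` holds the expert's own
    per-subject scores on the same ground truth. Besides the per-expert
    cells, a "mean" column tests the pipeline's average score across the
    expert-specific ground truths against the average across experts.
    """
    experts = list(expert_scores)
    if not experts:
        raise ValueError("no expert scores provided")
    metrics = list(next(iter(expert_scores.values())))
    rows = []
    for pipe, per_expert in pipeline_scores.items():
        missing = [e for e in experts if e not in per_expert]
        if missing:
            raise ValueError(f"pipeline {pipe!r} lacks scores on the ground "
                             f"truths of experts {missing}")
        for metric, expert in itertools.product(metrics, experts + ["mean"]):
            if expert == "mean":
                y = np.mean([np.asarray(expert_scores[e][metric])
                             for e in experts], axis=0)
                x = np.mean([np.asarray(per_expert[e][metric])
                             for e in experts], axis=0)
            else:
                y = np.asarray(expert_scores[expert][metric])
                x = np.asarray(per_expert[expert][metric])
            try:
                res = noninferiority_test(y, x, margin=margin, alpha=alpha)
                row = {"mean_difference": res.mean_difference,
                       "t": res.t_statistic, "p_value": res.p_value,
                       "significant": res.reject_h0, "n": res.n}
            except DegenerateDataError:
                # zero-variance differences: report the cell, not a p-value
                row = {"mean_difference": float(np.mean(y - x)),
                       "t": np.nan, "p_value": np.nan,
                       "significant": False, "n": y.size}
            rows.append({"pipeline": pipe, "metric": metric,
                         "expert": expert, **row})
    return pd.DataFrame(rows)
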