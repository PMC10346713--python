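"""Statistical comparison of CV accuracies and the scenario report grid.

True-label accuracies are compared to the ground-truth condition by paired
t-tests across replicates; randomized-label accuracies are compared to
chance (50% for binary problems) by one-sample t-tests.  Tests are
two-sided.  Degenerate inputs (zero-variance, zero-mean differences) take
the convention ``t = 0, p = 1``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .crossval import CVResult

__all__ = [
    "StatResult",
    "ScenarioReport",
    "paired_ttest",
    "one_sample_ttest",
    "build_report",
    "CHANCE_LEVEL",
]

#: chance accuracy for a balanced binary problem, in percent
CHANCE_LEVEL = 50.0


@dataclasses.dataclass
class StatResult:
    """Outcome of one two-sided t-test on accuracy values (percent)."""

    comparison: str  # "paired_vs_gt" | "one_sample_vs_chance"
    t_stat: float
    df: int
    p_value: float
    mean_difference: float  # percentage points
    n: int


def _t_from_diffs(diffs: np.ndarray, comparison: str) -> StatResult:
    n = len(diffs)
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            t, p = 0.0, 1.0
        else:
            t = float(np.inf) if mean > 0 else float(-np.inf)
            p = 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(2.0 * sst.t.sf(abs(t), df=n - 1))
    return StatResult(
        comparison=comparison, t_stat=float(t), df=n - 1, p_value=p, mean_difference=mean, n=n
    )


def paired_ttest(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided paired t-test on accuracy vectors paired by replicate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    return _t_from_diffs(a - b, "paired_vs_gt")


def one_sample_ttest(a: Sequence[float], mu: float = CHANCE_LEVEL) -> StatResult:
    """Two-sided one-sample t-test of accuracies against a reference level."""
    a = np.asarray(a, dtype=float)
    if a.size < 2:
        raise ValueError("one-sample t-test needs at least 2 values")
    return _t_from_diffs(a - mu, "one_sample_vs_chance")


def _holm(pvals: list[float]) -> list[float]:
    """Holm step-down adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


class ScenarioReport:
    """Grid of per-scenario, per-condition accuracies with significance flags.

    Rows are (scenario, condition) cells carrying the mean accuracy across
    replicates, the signed difference from the cell's reference (the
    ground-truth condition for true-label cells, chance for randomized
    cells), the t-test outcome and a significance flag at the configured
    alpha.  Flags derive only from the stored t-tests, so rebuilding the
    report from serialized results reproduces it exactly.
    """

    def __init__(self, table: pd.DataFrame, alpha: float, holm: bool = False):
        self.table = table.reset_index(drop=True)
        self.alpha = alpha
        self.holm = holm

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "holm": self.holm,
            "cells": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioReport":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["cells"]), payload["alpha"], payload["holm"])


def _replicate_means(values) -> np.ndarray:
    out = []
    for v in values:
        out.append(v.mean_accuracy if isinstance(v, CVResult) else float(v))
    return np.asarray(out, dtype=float)


def build_report(
    results: Mapping[str, Mapping[str, Sequence]],
    alpha: float = 0.05,
    holm: bool = False,
) -> ScenarioReport:
    """Assemble the scenario grid from per-replicate CV results.

    ``results`` maps a scenario key to a mapping of condition name to a
    list of per-replicate accuracies (floats in percent, or
    :class:`~trialcv.crossval.CVResult` objects whose mean is taken).
    Every scenario must contain a ``"gt"`` condition; conditions whose name
    contains ``"rand"`` are tested against chance (50%), all others against
    the scenario's ground truth by a paired test.  ``holm`` applies a Holm
    step-down correction across all cells (off by default, matching
    per-scenario individual testing).
    """
    missing = [k for k, conds in results.items() if "gt" not in conds]
    if missing:
        raise ValueError(f"scenarios missing a ground-truth condition: {missing}")

    rows = []
    for scenario in sorted(results):
        conds = results[scenario]
        gt = _replicate_means(conds["gt"])
        rows.append(
            {
                "scenario": scenario,
                "condition": "gt",
                "mean_accuracy_pct": float(np.mean(gt)),
                "reference": "",
                "mean_difference_pct": 0.0,
                "t_stat": np.nan,
                "df": np.nan,
                "p_value": np.nan,
                "n": len(gt),
            }
        )
        for condition in sorted(c for c in conds if c != "gt"):
            vals = _replicate_means(conds[condition])
            reference = "chance" if "rand" in condition else "gt"
            if len(vals) < 2:
                # a single replicate has no sampling variance to test against
                diff = float(np.mean(vals) - (CHANCE_LEVEL if reference == "chance" else np.mean(gt)))
                res = StatResult("untested", np.nan, 0, np.nan, diff, len(vals))
            elif reference == "chance":
                res = one_sample_ttest(vals, CHANCE_LEVEL)
            else:
                res = paired_ttest(vals, gt)
            rows.append(
                {
                    "scenario": scenario,
                    "condition": condition,
                    "mean_accuracy_pct": float(np.mean(vals)),
                    "reference": reference,
                    "mean_difference_pct": res.mean_difference,
                    "t_stat": res.t_stat,
                    "df": res.df,
                    "p_value": res.p_value,
                    "n": res.n,
                }
            )
    table = pd.DataFrame(rows)
    tested = table["p_value"].notna()
    pvals = table.loc[tested, "p_value"].tolist()
    if holm and pvals:
        table.loc[tested, "p_adjusted"] = _holm(pvals)
    else:
        table["p_adjusted"] = table["p_value"]
    table["significant"] = table["p_adjusted"] < alpha
    table.loc[~tested, "significant"] = False
    table["direction"] = np.where(
        table["mean_difference_pct"] > 0, "over", np.where(table["mean_difference_pct"] < 0, "under", "equal")
    )
    table.loc[table["condition"] == "gt", "direction"] = ""
    return ScenarioReport(table, alpha=alpha, holm=holm)
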