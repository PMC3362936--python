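"""Significance conventions and breeding-value summaries.

Variance components are tested one-tailed: significant when the estimate
minus 0.98 standard errors stays above zero. Correlations are tested
two-tailed: significant when |estimate| exceeds 1.96 standard errors.
These multipliers are reporting conventions of the analysis, not
likelihood-ratio tests (documented in the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

VARIANCE_MULTIPLIER = 0.98
CORRELATION_MULTIPLIER = 1.96


@dataclass
class SignificanceCall:
    estimate: float
    se: float
    rule: str  # "variance-one-tailed" | "correlation-two-tailed"
    significant: bool


def variance_significant(estimate: float, se: float) -> SignificanceCall:
    """One-tailed test for a variance or variance ratio."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if estimate < 0:
        warnings.warn("negative variance estimate; flagged not significant")
        return SignificanceCall(estimate, se, "variance-one-tailed", False)
    sig = estimate - VARIANCE_MULTIPLIER * se > 0
    return SignificanceCall(estimate, se, "variance-one-tailed", bool(sig))


def correlation_significant(estimate: float, se: float) -> SignificanceCall:
    """Two-tailed test for a correlation."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if abs(estimate) > 1 + 1e-9:
        raise ValueError("correlation outside [-1, 1]")
    sig = abs(estimate) - CORRELATION_MULTIPLIER * se > 0
    return SignificanceCall(estimate, se, "correlation-two-tailed", bool(sig))


def significance_table(report) -> pd.DataFrame:
    """Apply the variance rule to every component of a VarianceReport."""
    rows = []
    for name, est, se in zip(report.names, report.estimates, report.se):
        is_var = ":var(" in name
        if is_var:
            call = variance_significant(max(est, 0.0), se if np.isfinite(se) else 0.0)
        else:
            # covariances reported with the two-tailed convention
            sig = np.isfinite(se) and abs(est) - CORRELATION_MULTIPLIER * se > 0
            call = SignificanceCall(est, se, "correlation-two-tailed", bool(sig))
        rows.append(
            {"component": name, "estimate": est, "se": se, "rule": call.rule,
             "significant": call.significant}
        )
    return pd.DataFrame(rows)


def ebv_summary(solutions: dict, table: pd.DataFrame, group: str,
                column: str = "slope", bins: int = 20,
                offset: float = 0.0) -> dict:
    """Range and histogram of intercept/slope solutions for a pedigree group.

    group: 'offspring' (animal EBVs of recorded birds), 'sires' (animal
    EBVs of their sires) or 'dams' (maternal-effect solutions of the dams).
    `offset` shifts the solutions (e.g. by the fixed population slope, so
    tolerance EBVs are reported on the total-slope scale).
    """
    if group in ("offspring", "sires"):
        sol = solutions["animal"]
        ids = (
            table["animal_id"].astype(str).unique()
            if group == "offspring"
            else table["sire_id"].astype(str).dropna().unique()
        )
    elif group == "dams":
        sol = solutions["dam"]
        ids = table["dam_id"].astype(str).dropna().unique()
    else:
        raise ValueError(f"unknown group {group!r}")
    ids = [i for i in ids if i in sol.index]
    if len(ids) == 0:
        raise ValueError(f"no animals in group {group!r}")
    if column not in sol.columns:
        column = sol.columns[-1]
    vals = sol.loc[ids, column].to_numpy(dtype=float) + offset
    hist, edges = np.histogram(vals, bins=bins)
    return {
        "group": group,
        "column": column,
        "n": len(vals),
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        "hist_counts": hist.tolist(),
        "hist_edges": edges.tolist(),
    }
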