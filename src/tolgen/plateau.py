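"""Plateau-linear severity coding and threshold selection.

Body weight is expected to respond to heart ratio only above a disease
threshold: healthy birds sit on a plateau, affected birds on a declining
line. The severity covariate is therefore

    RATIOPlat = max(0, RATIO - threshold),

with the threshold (default 29%) selectable by an information-criterion
scan over candidate values. Residual heterogeneity along the severity axis
is handled by five classes: RATIOPlat = 0, (0,5], (5,10], (10,15], >15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 29.0
DEFAULT_CANDIDATES = (27.0, 28.0, 29.0, 30.0)
DEFAULT_CLASS_EDGES = (0.0, 5.0, 10.0, 15.0)


@dataclass
class PlateauConfig:
    threshold: float = DEFAULT_THRESHOLD
    candidate_range: tuple = DEFAULT_CANDIDATES
    residual_class_edges: tuple = DEFAULT_CLASS_EDGES

    def __post_init__(self):
        if self.threshold not in self.candidate_range:
            raise ValueError("threshold must be one of the candidates")
        e = np.asarray(self.residual_class_edges)
        if np.any(np.diff(e) <= 0) or e[0] != 0:
            raise ValueError("class edges must start at 0 and increase")


def code_ratioplat(ratio, threshold: float = DEFAULT_THRESHOLD):
    """Plateau-coded severity: 0 at or below the threshold, RATIO - threshold
    above it. Accepts scalars or arrays."""
    r = np.asarray(ratio, dtype=float)
    out = np.maximum(0.0, r - threshold)
    return float(out) if np.isscalar(ratio) else out


def back_transform(ratioplat, threshold: float = DEFAULT_THRESHOLD):
    """Severity back to the original heart-ratio scale (inverse of
    :func:`code_ratioplat` on the affected branch)."""
    t = np.asarray(ratioplat, dtype=float)
    if np.any(t < 0):
        raise ValueError("RATIOPlat must be non-negative")
    out = t + threshold
    return float(out) if np.isscalar(ratioplat) else out


def residual_class(ratioplat, edges: tuple = DEFAULT_CLASS_EDGES):
    """Residual class 1..k+1 for severity values: class 1 is exactly zero,
    the remaining classes are the left-open intervals between the edges."""
    t = np.asarray(ratioplat, dtype=float)
    if np.any(t < 0):
        raise ValueError("RATIOPlat must be non-negative")
    e = np.asarray(edges, dtype=float)
    cls = np.searchsorted(e[1:], t, side="left") + 2  # classes 2..k+1
    cls = np.where(t == 0.0, 1, cls)
    cls = cls.astype(np.int64)
    return int(cls) if np.isscalar(ratioplat) else cls


def aic_bic(logl: float, k: int, n: int) -> tuple:
    """AIC = -2 logL + 2k, BIC = -2 logL + k ln(n), with k the number of
    variance parameters and n the record count (REML convention)."""
    return -2.0 * logl + 2.0 * k, -2.0 * logl + k * np.log(n)


def threshold_scan(table: pd.DataFrame, ped, candidates=DEFAULT_CANDIDATES,
                   include_linear: bool = False, **fit_options):
    """Fit the random-regression tolerance model at each candidate plateau
    threshold and rank by AIC/BIC.

    Returns (DataFrame with one row per candidate, selected threshold).
    Non-converged candidates are flagged and excluded from the argmin. With
    `include_linear`, an extra row fits the fully linear model (severity =
    RATIO - threshold without plateau-capping) for comparison.

    Candidates are ranked by information criteria computed from the full
    (ML) log-likelihood evaluated at the REML estimates: restricted
    likelihoods are not comparable between models whose severity covariate
    differs, because the fixed-design projection term changes with the
    coding.
    """
    from .models import fit_tolerance_model

    rows = []
    for thr in candidates:
        rep = None
        try:
            rep = fit_tolerance_model(table, ped, threshold=thr, **fit_options)
            ok = rep.converged
        except Exception:
            ok = False
        rows.append(
            {
                "threshold": thr,
                "model": "plateau",
                "logl": rep.logl if rep else np.nan,
                "logl_ml": rep.logl_ml if rep else np.nan,
                "aic": rep.aic_ml if rep else np.nan,
                "bic": rep.bic_ml if rep else np.nan,
                "converged": ok,
            }
        )
    if include_linear:
        try:
            rep = fit_tolerance_model(table, ped, threshold=None, **fit_options)
            rows.append(
                {
                    "threshold": np.nan,
                    "model": "linear",
                    "logl": rep.logl,
                    "logl_ml": rep.logl_ml,
                    "aic": rep.aic_ml,
                    "bic": rep.bic_ml,
                    "converged": rep.converged,
                }
            )
        except Exception:
            rows.append(
                {"threshold": np.nan, "model": "linear", "logl": np.nan,
                 "logl_ml": np.nan, "aic": np.nan, "bic": np.nan,
                 "converged": False}
            )
    df = pd.DataFrame(rows)
    ok = df[(df.model == "plateau") & df.converged & df.aic.notna()]
    selected = float(ok.loc[ok.aic.idxmin(), "threshold"]) if len(ok) else np.nan
    return df, selected
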