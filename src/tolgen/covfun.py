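"""Covariance functions along the disease-severity trajectory.

A fitted random-regression model yields a 2x2 (co)variance matrix G over
(intercept, slope) at the genetic and at the maternal level. The variance
of 7-week body weight at severity t is the quadratic form

    V(t) = x' G x,     x = (1, t)',

and the genetic correlation between healthy birds (t = 0) and birds at
severity t is

    r(t) = x0' G xt / sqrt(x0' G x0 * xt' G xt)
         = (s00 + t s01) / sqrt(s00 (s00 + 2 t s01 + t^2 s11)).

Combining genetic and maternal trajectories with the class-specific
residual variances gives phenotypic variance V_P = V_G + V_M + V_E,
heritability h^2 = V_G/V_P and maternal ratio m^2 = V_M/V_P pointwise
along the trajectory, reported against back-transformed heart ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plateau import DEFAULT_CLASS_EDGES, DEFAULT_THRESHOLD, back_transform, residual_class


@dataclass
class GenCov2:
    """2x2 intercept/slope covariance block."""

    var_intercept: float
    var_slope: float
    cov: float

    @classmethod
    def from_correlation(cls, var_intercept, var_slope, corr) -> "GenCov2":
        return cls(var_intercept, var_slope, corr * np.sqrt(var_intercept * var_slope))

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.var_intercept, self.cov], [self.cov, self.var_slope]]
        )

    @property
    def correlation(self) -> float:
        return self.cov / np.sqrt(self.var_intercept * self.var_slope)

    def is_psd(self, tol: float = 1e-9) -> bool:
        return (
            self.var_intercept >= -tol
            and self.var_slope >= -tol
            and self.var_intercept * self.var_slope - self.cov**2 >= -tol
        )


def trajectory_variance(g: GenCov2, t) -> np.ndarray | float:
    """x' G x at severity t (scalar or array): s00 + 2 t s01 + t^2 s11."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("severity must be non-negative")
    out = g.var_intercept + 2.0 * tt * g.cov + tt**2 * g.var_slope
    return float(out) if np.isscalar(t) else out


def correlation_with_healthy(g: GenCov2, t) -> np.ndarray | float:
    """Genetic correlation between severity 0 and severity t."""
    if g.var_intercept <= 0:
        raise ValueError("intercept variance must be positive")
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("severity must be non-negative")
    num = g.var_intercept + tt * g.cov
    den = np.sqrt(g.var_intercept * trajectory_variance(g, tt))
    out = num / den
    return float(out) if np.isscalar(t) else out


def trajectory_ratios(
    g_gen: GenCov2,
    g_mat: GenCov2,
    v_e_by_class: np.ndarray,
    grid: np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    class_edges=DEFAULT_CLASS_EDGES,
    mean_intercept: float | None = None,
    population_slope: float | None = None,
) -> pd.DataFrame:
    """Variance, heritability and maternal-ratio trajectories on a severity
    grid (default 0..20 by 0.5, i.e. heart ratio 29-49%).

    V_E at each grid point is the residual variance of the class containing
    the point; when the trait mean trajectory (mean_intercept +
    population_slope * t) is supplied, a phenotypic CV column is added.
    """
    if grid is None:
        grid = np.arange(0.0, 20.0 + 1e-9, 0.5)
    grid = np.asarray(grid, dtype=float)
    cls = residual_class(grid, class_edges)
    v_e = np.asarray(v_e_by_class, dtype=float)[cls - 1]
    v_g = trajectory_variance(g_gen, grid)
    v_m = trajectory_variance(g_mat, grid)
    v_p = v_g + v_m + v_e
    if np.any(v_p <= 0):
        raise ValueError("non-positive phenotypic variance on the grid")
    out = pd.DataFrame(
        {
            "ratioplat": grid,
            "heart_ratio": back_transform(grid, threshold),
            "residual_class": cls,
            "v_g": v_g,
            "v_m": v_m,
            "v_e": v_e,
            "v_p": v_p,
            "h2": v_g / v_p,
            "m2": v_m / v_p,
            "r_with_healthy": correlation_with_healthy(g_gen, grid),
        }
    )
    if mean_intercept is not None and population_slope is not None:
        mean_bw7 = mean_intercept + population_slope * grid
        out["cv_percent"] = 100.0 * np.sqrt(v_p) / mean_bw7
    return out


def variance_ratios(v_g: float, v_m: float, v_e: float) -> tuple:
    """(h^2, m^2) from a single set of components."""
    v_p = v_g + v_m + v_e
    return v_g / v_p, v_m / v_p
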