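"""Reliability coefficients: ICC, effective error, ICC2, D-study curves.

Two levels of reliability are distinguished.  The observed-variable
intra-class correlation,

    ICC = sigma_T^2 / (sigma_T^2 + sum of all error variances),

is the reliability of a *single* measurement for telling persons apart.
Construct-level reliability ICC2 asks how precisely the whole
multi-occasion design measures the latent true score:

    ICC2 = sigma_T^2 / (sigma_T^2 + sigma_eff^2),

where the *effective error* sigma_eff^2 is the error variance of a
hypothetical single direct measurement of the true score that is
power-equivalent to the full design.  With unit loadings the
generalized-least-squares precision of the latent factor gives it in
closed form:

    sigma_eff^2 = 1 / (1' Sigma_E^{-1} 1),

with Sigma_E the model-implied covariance of the error part alone
(true-score variance removed).  When all facet variances vanish this
reduces to the classical sigma_E^2 / n for n occasions, so ICC2 recovers
the Spearman-Brown-style formula sigma_T^2 / (sigma_T^2 + sigma_E^2/n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .design import (Design, VarianceComponents, error_covariance,
                     validate_design)

__all__ = ["ReliabilityReport", "icc", "effective_error", "icc2",
           "standardized_shares", "reliability_report", "reliability_curve"]


def icc(theta: VarianceComponents) -> float:
    """Observed-variable intra-class correlation of a single measurement.

    The ratio of between-person (true-score) variance to total variance;
    equivalently the model-implied correlation between two occasions
    sharing no facet level.
    """
    total = theta.total_variance
    if total <= 0:
        raise ValueError("total variance must be > 0")
    return float(theta.sigma_T2 / total)


def effective_error(design: Design, theta: VarianceComponents) -> float:
    """Effective error variance of the design for measuring the true score.

    GLS precision of the unit-loading latent factor:
    ``1 / (1' Sigma_E^{-1} 1)`` with Sigma_E the error-only covariance.
    Weakly decreases as occasions are added, and equals sigma_E^2 / n
    when every facet variance is zero.
    """
    validate_design(design)
    sigma_e = error_covariance(design, theta)
    ones = np.ones(design.n_occasions)
    try:
        chol = np.linalg.cholesky(sigma_e)
    except np.linalg.LinAlgError:
        raise ValueError("error covariance is singular (needs sigma_E2 > 0)")
    z = np.linalg.solve(chol, ones)
    precision = float(z @ z)
    return 1.0 / precision


def icc2(design: Design, theta: VarianceComponents) -> float:
    """Construct-level reliability of the whole design.

    ``sigma_T^2 / (sigma_T^2 + effective error)``; always at least as
    large as the single-measurement ICC because averaging over
    occasions can only shrink the error.
    """
    eff = effective_error(design, theta)
    denom = theta.sigma_T2 + eff
    if denom <= 0:
        raise ValueError("sigma_T2 + effective error must be > 0")
    return float(theta.sigma_T2 / denom)


def standardized_shares(theta: VarianceComponents) -> dict:
    """Share of total variance per component, keyed by parameter name.

    Shares sum to one; the true-score share equals the ICC.
    """
    total = theta.total_variance
    if total <= 0:
        raise ValueError("total variance must be > 0")
    shares = {"sigma_T2": theta.sigma_T2 / total}
    for f, v in theta.facet_variances.items():
        shares[f] = v / total
    shares["sigma_E2"] = theta.sigma_E2 / total
    return {k: float(v) for k, v in shares.items()}


@dataclass(frozen=True)
class ReliabilityReport:
    """ICC, effective error, ICC2 and standardized shares for one design."""

    icc: float
    sigma_eff2: float
    icc2: float
    shares: Mapping[str, float]

    def __str__(self) -> str:
        parts = [f"ICC = {self.icc:.2f}",
                 f"effective error = {self.sigma_eff2:.4f}",
                 f"ICC2 = {self.icc2:.2f}"]
        share_txt = ", ".join(f"{k}: {100 * v:.0f}%" for k, v in self.shares.items())
        return "; ".join(parts) + f"; shares: {share_txt}"


def reliability_report(design: Design, theta: VarianceComponents) -> ReliabilityReport:
    """Bundle ICC, effective error, ICC2 and shares for a design + components."""
    return ReliabilityReport(
        icc=icc(theta),
        sigma_eff2=effective_error(design, theta),
        icc2=icc2(design, theta),
        shares=standardized_shares(theta),
    )


def reliability_curve(design_template: Callable[[int], Design],
                      theta: VarianceComponents, vary: str,
                      values: Iterable[int]) -> pd.DataFrame:
    """D-study: trace ICC2 as a design factor varies.

    Parameters
    ----------
    design_template
        Callable mapping a factor value to a valid
        :class:`~iced.design.Design` (e.g. ``lambda r:
        make_nested_design(2, 2, r)`` to vary runs per session).
    theta
        Variance components, held fixed across designs.
    vary
        Name of the varied factor (labels the output column).
    values
        Factor values to evaluate.

    Returns
    -------
    DataFrame with columns ``[vary, "n_occasions", "sigma_eff2", "icc2"]``,
    one row per factor value.
    """
    rows = []
    for v in values:
        design = design_template(v)
        validate_design(design)
        eff = effective_error(design, theta)
        rows.append({vary: v, "n_occasions": design.n_occasions,
                     "sigma_eff2": eff,
                     "icc2": float(theta.sigma_T2 / (theta.sigma_T2 + eff))})
    return pd.DataFrame(rows)
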