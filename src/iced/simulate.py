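"""Synthetic repeated-measures data with orthogonal variance components.

Data are generated exactly under the measurement model being estimated:
for person p at occasion o,

    y_{p,o} = mu + T_p + sum_f u^{(p)}_{f, level_f(o)} + e_{p,o},

with every term an independent zero-mean Gaussian draw at the stated
variance.  Facet effects are person-specific nuisances (a fresh day or
session effect per person), not calendar effects shared across persons.
The module also provides the joint longitudinal + cross-sectional
layout — a small deeply-measured sample stacked with a large
single-occasion sample under a mutually exclusive missingness pattern —
and a parameter-recovery harness for the FIML estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .design import (Design, VarianceComponents, build_membership,
                     check_identifiability, validate_design)

__all__ = ["SimulationSpec", "simulate_dataset", "simulate_joint",
           "aggregated_cv", "parameter_recovery"]


@dataclass(frozen=True)
class SimulationSpec:
    """What to simulate: design, generating components, sample size, seed."""

    design: Design
    theta: VarianceComponents
    n_persons: int
    seed: int = 0
    missing_pattern: Callable | None = field(default=None)

    def __post_init__(self):
        validate_design(self.design)
        if not self.theta.matches(self.design):
            raise ValueError("theta facets do not match design facets")
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")


def simulate_dataset(spec: SimulationSpec) -> Dataset:
    """Draw a person-by-occasion dataset from the parallel model.

    Deterministic given the seed.  If ``spec.missing_pattern`` is set it
    is called with ``(rng, n_persons, n_occasions)`` and must return a
    boolean observed-mask; masked-out cells become missing.
    """
    design, theta = spec.design, spec.theta
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_persons, design.n_occasions
    y = np.full((n, p), float(theta.mu))
    y += rng.normal(0.0, np.sqrt(theta.sigma_T2), size=(n, 1))
    for f in design.facets:
        Z = build_membership(design, f)
        sd = np.sqrt(theta.facet_variances[f])
        u = rng.normal(0.0, sd, size=(n, Z.shape[1]))  # per-person level effects
        y += u @ Z.T
    y += rng.normal(0.0, np.sqrt(theta.sigma_E2), size=(n, p))
    if spec.missing_pattern is not None:
        mask = np.asarray(spec.missing_pattern(rng, n, p), dtype=bool)
        y = np.where(mask, y, np.nan)
    frame = pd.DataFrame(y, index=[f"p{i + 1}" for i in range(n)],
                         columns=list(design.occasions))
    return Dataset(frame)


def joint_design(design_long: Design, cross_occasion: str = "Tx") -> Design:
    """Longitudinal design extended by one cross-sectional occasion.

    The extra occasion gets a fresh level on every facet (it shares no
    day/session with the longitudinal occasions), so it informs only
    the between-person variance.
    """
    if cross_occasion in design_long.occasions:
        raise ValueError(f"occasion {cross_occasion!r} already in design")
    occasions = list(design_long.occasions) + [cross_occasion]
    membership = {}
    for f in design_long.facets:
        m = dict(design_long.membership[f])
        m[cross_occasion] = f"{cross_occasion}_{f}"
        membership[f] = m
    return Design(occasions, design_long.facets, membership)


def simulate_joint(spec_long: SimulationSpec, n_cross: int,
                   seed: int | None = None,
                   cross_occasion: str = "Tx") -> Dataset:
    """Stack longitudinal and cross-sectional samples, mutually missing.

    Longitudinal persons are observed on all occasions of
    ``spec_long.design`` and missing on the cross-sectional occasion;
    cross-sectional persons are observed on that single occasion only.
    Both arms are generated from the same variance components, so a
    joint FIML fit pools them: the cross-sectional arm sharpens the
    between-person variance while the longitudinal arm pins down the
    within-person components.

    With ``n_cross=0`` the result is identical to
    :func:`simulate_dataset` on ``spec_long``.
    """
    if n_cross < 0:
        raise ValueError("n_cross must be >= 0")
    if spec_long.design.n_occasions < 2:
        raise ValueError("longitudinal design needs >= 2 occasions")
    long_data = simulate_dataset(spec_long)
    if n_cross == 0:
        return long_data
    seed = spec_long.seed if seed is None else seed
    design_x = joint_design(spec_long.design, cross_occasion)
    theta = spec_long.theta
    rng = np.random.default_rng(int(seed) + 1)
    # a cross-sectional observation = mu + T + (one level per facet) + e
    var_single = theta.total_variance
    x = rng.normal(theta.mu, np.sqrt(var_single), size=n_cross)
    wide = pd.DataFrame(np.nan, columns=list(design_x.occasions),
                        index=([f"long_{i}" for i in long_data.person_ids]
                               + [f"cross_p{j + 1}" for j in range(n_cross)]))
    wide.loc[wide.index[:long_data.n_persons],
             list(spec_long.design.occasions)] = long_data.values.to_numpy()
    wide.loc[wide.index[long_data.n_persons:], cross_occasion] = x
    group = pd.Series(["longitudinal"] * long_data.n_persons
                      + ["cross-sectional"] * n_cross, index=wide.index)
    return Dataset(wide, group)


def aggregated_cv(data: Dataset) -> float:
    """Aggregated coefficient of variation of a repeated-measures dataset.

    The square root of the average within-person variance, divided by
    the grand mean of all observed cells — the physicist's precision
    index, which is blind to between-person differences (unlike the
    ICC).  Requires a non-zero grand mean and at least one person with
    two or more observations.
    """
    values = data.values
    grand = float(np.nanmean(values.to_numpy()))
    if grand == 0:
        raise ValueError("grand mean is zero; CV undefined")
    counts = values.notna().sum(axis=1)
    eligible = values.loc[counts >= 2]
    if len(eligible) == 0:
        raise ValueError("no person has >= 2 observations")
    within = eligible.var(axis=1, ddof=1, skipna=True).mean()
    return float(np.sqrt(within) / grand)


def parameter_recovery(design: Design, theta: VarianceComponents,
                       n_persons: int, n_reps: int, seed: int = 0,
                       restarts: int = 1, alpha: float = 0.05) -> pd.DataFrame:
    """Monte-Carlo parameter recovery for the FIML estimator.

    Simulates ``n_reps`` datasets from ``theta``, fits each, and
    tabulates per-parameter mean estimate, bias, relative bias, RMSE
    and coverage of the Wald ``1 - alpha`` interval (coverage is NaN
    for parameters whose SE was unavailable in every replicate).

    Refuses unidentified designs up front, attaching the
    identifiability report to the error.
    """
    from .model import ICEDModel

    report = check_identifiability(design)
    if not report.identified:
        err = ValueError(f"design is not identified; refusing recovery. {report}")
        err.identifiability = report
        raise err
    rng = np.random.default_rng(seed)
    names = ["sigma_T2", *design.facets, "sigma_E2"]
    truth = theta.named_variances()
    z = stats.norm.ppf(1 - alpha / 2)
    estimates = {n: [] for n in names}
    covered = {n: [] for n in names}
    for _ in range(n_reps):
        sub = int(rng.integers(0, 2**31 - 1))
        data = simulate_dataset(SimulationSpec(design, theta, n_persons, seed=sub))
        fit = ICEDModel(data, design).fit(restarts=restarts, seed=sub,
                                          compute_se=True)
        for n in names:
            est = fit.params[n]
            estimates[n].append(est)
            se = fit.se.get(n, np.nan)
            if np.isfinite(se) and se > 0:
                covered[n].append(abs(est - truth[n]) <= z * se)
    rows = []
    for n in names:
        est = np.asarray(estimates[n])
        bias = est.mean() - truth[n]
        rows.append({
            "parameter": n,
            "truth": truth[n],
            "mean_estimate": est.mean(),
            "bias": bias,
            "relative_bias": bias / truth[n] if truth[n] > 0 else np.nan,
            "rmse": float(np.sqrt(np.mean((est - truth[n]) ** 2))),
            "coverage": float(np.mean(covered[n])) if covered[n] else np.nan,
            "n_reps": n_reps,
        })
    return pd.DataFrame(rows).set_index("parameter")
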