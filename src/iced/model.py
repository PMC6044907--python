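"""FIML estimation of variance components for repeated-measures designs.

The model is a parallel measurement model with orthogonal random
effects: each observation is the sum of a common mean, a person-level
true score, one random effect per facet level (day, session, ...) and a
residual.  Estimation maximises the full-information maximum-likelihood
(FIML) criterion: each person contributes the multivariate-normal
log-density of their *observed* cells under the model-implied mean and
covariance restricted to those cells, which is valid under data missing
at random.  Variances are constrained to be non-negative, so estimates
can land on the zero boundary (flagged in the results).

The public surface is statsmodels-like: build an :class:`ICEDModel`
from a :class:`~iced.data.Dataset` and a :class:`~iced.design.Design`,
call :meth:`~ICEDModel.fit`, and read estimates, standard errors,
likelihood-ratio and Wald tests, and reliability coefficients off the
returned :class:`ICEDResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import Dataset
from .design import (Design, VarianceComponents, model_implied_covariance,
                     validate_design)

__all__ = [
    "ICEDModel", "ICEDResults", "MultigroupICEDModel", "MultigroupResults",
    "TestResult", "fiml_loglik", "fit_fiml", "wald_test", "lrt",
    "fit_multigroup", "interaction_lrt", "standardize",
]

_LOGLIK_PENALTY = 1e12  # objective value returned on a non-PD covariance

_ALIASES = {"true_score": "sigma_T2", "t": "sigma_T2",
            "residual": "sigma_E2", "e": "sigma_E2"}


def canonical_component(design: Design, name: str) -> str:
    """Map user-facing component names onto internal parameter names."""
    key = _ALIASES.get(str(name).lower(), name)
    valid = ["sigma_T2", *design.facets, "sigma_E2"]
    if key not in valid:
        raise KeyError(f"unknown component {name!r}; expected one of {valid}")
    return key


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis test on a variance component."""

    statistic: float
    df: int
    p_value: float
    kind: str           # "LRT" or "Wald"
    component: str
    note: str = ""

    def __str__(self) -> str:
        return (f"{self.kind} for {self.component}: stat={self.statistic:.4f}, "
                f"df={self.df}, p={self.p_value:.4g}"
                + (f" ({self.note})" if self.note else ""))


class _ParameterMap:
    """Free-to-full parameter bookkeeping: zero-fixes and equality ties.

    Full parameters are ``mu`` (or one mean per occasion) followed by
    the variance components in design order.  A restricted model fixes
    components at values (usually 0) or ties several components to a
    single free value.
    """

    def __init__(self, design: Design, per_occasion_means: bool = False,
                 fixed: dict | None = None, ties: list | None = None):
        self.design = design
        if per_occasion_means:
            self.mean_names = [f"mu[{o}]" for o in design.occasions]
        else:
            self.mean_names = ["mu"]
        self.var_names = ["sigma_T2", *design.facets, "sigma_E2"]
        self.full_names = self.mean_names + self.var_names
        self.fixed = {canonical_component(design, k): float(v)
                      for k, v in (fixed or {}).items()}
        rep: dict[str, str] = {}
        for group in (ties or []):
            names = [canonical_component(design, n) for n in group]
            for n in names[1:]:
                rep[n] = names[0]
        self.tied_to = rep
        self.free_names = [n for n in self.full_names
                           if n not in self.fixed and n not in self.tied_to]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def bounds(self) -> list:
        return [(None, None) if n in self.mean_names else (0.0, None)
                for n in self.free_names]

    def expand(self, free: np.ndarray) -> dict:
        values = dict(zip(self.free_names, free))
        values.update(self.fixed)
        for name, master in self.tied_to.items():
            values[name] = values[master]
        return values

    def shrink(self, full: dict) -> np.ndarray:
        return np.array([full[n] for n in self.free_names], dtype=float)

    def mean_vector(self, values: dict) -> np.ndarray:
        if len(self.mean_names) == 1:
            return np.full(self.design.n_occasions, values["mu"])
        return np.array([values[n] for n in self.mean_names])

    def theta(self, values: dict) -> VarianceComponents:
        return VarianceComponents(
            sigma_T2=max(values["sigma_T2"], 0.0),
            facet_variances={f: max(values[f], 0.0) for f in self.design.facets},
            sigma_E2=max(values["sigma_E2"], 0.0),
            mu=float(np.mean(self.mean_vector(values))),
        )


class ICEDModel:
    """Variance-component decomposition of a repeated-measures design.

    Parameters
    ----------
    data
        Person-by-occasion :class:`~iced.data.Dataset`; missing cells
        allowed (handled by person-wise FIML).
    design
        The :class:`~iced.design.Design` mapping occasions to facet
        levels.  Dataset columns are aligned to the design's occasion
        order.
    per_occasion_means
        If true, estimate one mean per occasion instead of the single
        common mean of the parallel model.  Off by default.
    """

    def __init__(self, data: Dataset, design: Design,
                 per_occasion_means: bool = False):
        validate_design(design)
        self.design = design
        self.data = data.align(design.occasions)
        self.per_occasion_means = per_occasion_means
        # canonical person order (sorted ids) so results do not depend on
        # the row order of the input table, down to the last bit
        order = np.argsort(np.array(self.data.person_ids, dtype=str))
        y, mask = self.data.to_arrays()
        y, mask = y[order], mask[order]
        # group persons by missingness pattern: one Cholesky per pattern
        patterns, inverse = np.unique(mask, axis=0, return_inverse=True)
        self._patterns = []
        for g, pat in enumerate(patterns):
            rows = np.nonzero(inverse == g)[0]
            idx = np.nonzero(pat)[0]
            self._patterns.append((idx, y[np.ix_(rows, idx)]))
        self.n_persons = self.data.n_persons
        self.n_obs = int(mask.sum())

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, design: Design,
                       person_col: str | None = None, **kwargs) -> "ICEDModel":
        """Build from a wide DataFrame (person id in ``person_col`` or index)."""
        return cls(Dataset.from_wide(frame, person_col=person_col), design, **kwargs)

    # -- likelihood ---------------------------------------------------
    def loglik(self, theta: VarianceComponents) -> float:
        """FIML log-likelihood at a parameter point.

        Sums, over persons, the log multivariate-normal density of each
        person's observed subvector under the model-implied mean and
        the matching submatrix of the covariance.
        """
        sigma = model_implied_covariance(self.design, theta)
        mean = np.full(self.design.n_occasions, theta.mu)
        return self._loglik_from(mean, sigma)

    def _loglik_from(self, mean: np.ndarray, sigma: np.ndarray) -> float:
        ll = 0.0
        for idx, ymat in self._patterns:
            sub = sigma[np.ix_(idx, idx)]
            try:
                chol = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return -np.inf
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            resid = ymat - mean[idx]
            z = np.linalg.solve(chol, resid.T)
            quad = float(np.sum(z * z))
            n_g, p_g = ymat.shape
            ll += -0.5 * (n_g * p_g * np.log(2 * np.pi) + n_g * logdet + quad)
        return ll

    def _objective(self, pmap: _ParameterMap):
        def neg_loglik(free: np.ndarray) -> float:
            values = pmap.expand(free)
            theta = pmap.theta(values)
            sigma = model_implied_covariance(self.design, theta)
            mean = pmap.mean_vector(values)
            ll = self._loglik_from(mean, sigma)
            if not np.isfinite(ll):
                return _LOGLIK_PENALTY
            return -ll
        return neg_loglik

    # -- starting values ----------------------------------------------
    def _start_values(self, pmap: _ParameterMap) -> dict:
        df = self.data.values.sort_index()  # order-invariant moments
        grand = float(np.nanmean(df.to_numpy()))
        person_means = df.mean(axis=1, skipna=True)
        within = df.var(axis=1, ddof=1, skipna=True).mean()
        if not np.isfinite(within) or within <= 0:
            within = max(0.1 * df.to_numpy()[~np.isnan(df.to_numpy())].var(), 1e-3)
        k_bar = df.notna().sum(axis=1).mean()
        between = max(float(person_means.var(ddof=1)) - within / max(k_bar, 1.0),
                      0.1 * within)
        n_err = 1 + len(self.design.facets)
        start = {"mu": grand, "sigma_T2": between, "sigma_E2": within / n_err}
        for f in self.design.facets:
            start[f] = within / n_err
        for name in pmap.mean_names:
            start.setdefault(name, grand)
        return start

    # -- fitting ------------------------------------------------------
    def fit(self, fixed: dict | None = None, ties: list | None = None,
            restarts: int = 5, seed: int = 0, tol: float = 1e-10,
            compute_se: bool = True, start: dict | None = None) -> "ICEDResults":
        """Maximise the FIML likelihood under non-negativity constraints.

        Parameters
        ----------
        fixed
            Components fixed at a value, e.g. ``{"session": 0.0}`` for a
            restricted model.
        ties
            Groups of components constrained equal, e.g.
            ``[("session", "residual")]``.
        restarts
            Number of random restarts around method-of-moments starting
            values; the best converged optimum is kept.
        seed
            Seed for restart perturbations (deterministic fits).
        compute_se
            Whether to compute standard errors from the observed
            information (numerical Hessian) at the optimum.
        """
        if self.n_persons < 2:
            raise ValueError("need at least 2 persons to estimate variances")
        pmap = _ParameterMap(self.design, self.per_occasion_means, fixed, ties)
        neg_loglik = self._objective(pmap)
        base = self._start_values(pmap)
        if start:
            base.update(start)
        rng = np.random.default_rng(seed)
        bounds = pmap.bounds()

        best = None
        scale = max(abs(base.get("mu", 1.0)), 1.0)
        for attempt in range(1 + max(0, restarts)):
            trial = dict(base)
            if attempt > 0:
                for name in pmap.free_names:
                    if name in pmap.mean_names:
                        trial[name] = base[name] + 0.2 * scale * rng.standard_normal()
                    else:
                        trial[name] = base[name] * np.exp(0.7 * rng.standard_normal())
            x0 = pmap.shrink(trial)
            res = optimize.minimize(neg_loglik, x0, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"ftol": tol, "gtol": 1e-8,
                                             "maxiter": 500})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        assert best is not None
        converged = bool(best.success) and best.fun < _LOGLIK_PENALTY / 2
        values = pmap.expand(best.x)
        loglik = -float(best.fun)

        boundary = {n for n in pmap.var_names
                    if n not in pmap.tied_to and values[n] <= 1e-8}
        se = {}
        if compute_se and converged:
            se = self._standard_errors(neg_loglik, best.x, pmap, boundary)
        return ICEDResults(model=self, pmap=pmap, values=values,
                           loglik=loglik, se=se, converged=converged,
                           boundary_flags=frozenset(boundary),
                           optimizer_message=str(best.message))

    def _standard_errors(self, neg_loglik, xopt: np.ndarray,
                         pmap: _ParameterMap, boundary: set) -> dict:
        """SEs from the inverse observed information (central differences)."""
        n = len(xopt)
        h = np.maximum(1e-4 * np.abs(xopt), 1e-6)
        hess = np.zeros((n, n))
        f0 = neg_loglik(xopt)

        def f(x):
            val = neg_loglik(x)
            return val if val < _LOGLIK_PENALTY / 2 else np.nan

        for i in range(n):
            for j in range(i, n):
                xpp = xopt.copy(); xpp[i] += h[i]; xpp[j] += h[j]
                xmm = xopt.copy(); xmm[i] -= h[i]; xmm[j] -= h[j]
                xpm = xopt.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = xopt.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                if i == j:
                    hess[i, i] = (f(xpp) - 2 * f0 + f(xmm)) / (4 * h[i] * h[i])
                else:
                    hess[i, j] = hess[j, i] = ((f(xpp) - f(xpm) - f(xmp) + f(xmm))
                                               / (4 * h[i] * h[j]))
        se = {}
        with np.errstate(invalid="ignore"):
            try:
                cov = np.linalg.pinv(hess)
                diag = np.diag(cov)
                for k, name in enumerate(pmap.free_names):
                    v = diag[k]
                    se[name] = float(np.sqrt(v)) if np.isfinite(v) and v > 0 else np.nan
            except np.linalg.LinAlgError:
                se = {name: np.nan for name in pmap.free_names}
        for name in boundary:
            # curvature at the 0 bound is one-sided; the Wald SE is unreliable
            if name in se:
                se[name] = np.nan
        return se


class ICEDResults:
    """Fitted variance components with uncertainty, tests and reliability.

    Attributes
    ----------
    theta_hat : VarianceComponents
        Point estimates (non-negative variances, common mean).
    loglik : float
        Maximised FIML log-likelihood.
    se : dict
        Standard error per free parameter (observed information); NaN
        at boundary estimates, where the Wald approximation fails.
    boundary_flags : frozenset
        Variance parameters estimated at the zero bound.
    """

    def __init__(self, model: ICEDModel, pmap: _ParameterMap, values: dict,
                 loglik: float, se: dict, converged: bool,
                 boundary_flags: frozenset, optimizer_message: str = ""):
        self.model = model
        self._pmap = pmap
        self.params = dict(values)
        self.loglik = float(loglik)
        self.se = dict(se)
        self.converged = converged
        self.boundary_flags = boundary_flags
        self.optimizer_message = optimizer_message
        self.n_persons = model.n_persons
        self.theta_hat = pmap.theta(values)

    @property
    def df_model(self) -> int:
        return self._pmap.n_free

    # -- inference ----------------------------------------------------
    def wald_test(self, component: str) -> TestResult:
        """Wald chi-square test (1 df) of a component against zero.

        The statistic is ``(estimate / SE)^2`` referred to chi2(1) —
        the convention under which a variance can be tested even when
        the null model cannot be refitted (e.g. the residual term).
        """
        name = canonical_component(self.model.design, component)
        if not self.converged:
            raise RuntimeError("Wald test unavailable: fit did not converge")
        if name not in self._pmap.free_names:
            raise ValueError(f"{component!r} is not a free parameter of this fit")
        est = self.params[name]
        if name in self.boundary_flags:
            warnings.warn(f"{name} estimated at the zero bound; the Wald "
                          "approximation is invalid there", stacklevel=2)
            return TestResult(0.0, 1, 1.0, "Wald", name, note="boundary estimate")
        s = self.se.get(name, np.nan)
        if not np.isfinite(s) or s <= 0:
            raise RuntimeError(f"no standard error available for {name}")
        stat = (est / s) ** 2
        return TestResult(float(stat), 1, float(stats.chi2.sf(stat, 1)),
                          "Wald", name)

    def lrt(self, component: str, mixture: bool = False, **fit_kwargs) -> TestResult:
        """Likelihood-ratio test of a single variance component = 0.

        Refits the model with the component fixed at zero and refers
        ``-2 (loglik_restricted - loglik_full)`` to chi2(1).  The null
        value lies on the boundary of the parameter space, so the
        chi2(1) reference is conservative; ``mixture=True`` uses the
        50:50 chi2(0):chi2(1) mixture instead, which is the
        statistically preferable reference for a variance-at-zero null.

        The residual variance cannot be dropped — without it the
        restricted covariance is singular for any within-session pair —
        so requesting it raises, pointing to :meth:`wald_test`.
        """
        name = canonical_component(self.model.design, component)
        if name == "sigma_E2":
            raise ValueError(
                "the residual variance cannot be fixed at zero (the restricted "
                "model has a singular covariance and is not estimable); use "
                "wald_test('residual') instead")
        if name == "sigma_T2" or name in self.model.design.facets:
            restricted = self.model.fit(fixed={name: 0.0},
                                        compute_se=False, **fit_kwargs)
        else:  # pragma: no cover - canonical_component already validated
            raise KeyError(name)
        return self._lr_from(restricted.loglik, 1, name, mixture)

    def lrt_equal(self, component_a: str, component_b: str,
                  mixture: bool = False, **fit_kwargs) -> TestResult:
        """1-df LRT of equality of two variance components.

        The restricted model estimates a single shared variance for
        both components (an interior null, so the plain chi2(1)
        reference applies).
        """
        a = canonical_component(self.model.design, component_a)
        b = canonical_component(self.model.design, component_b)
        restricted = self.model.fit(ties=[(a, b)], compute_se=False, **fit_kwargs)
        return self._lr_from(restricted.loglik, 1, f"{a}={b}", mixture=False)

    def _lr_from(self, loglik_restricted: float, df: int, label: str,
                 mixture: bool) -> TestResult:
        stat = -2.0 * (loglik_restricted - self.loglik)
        tol = 1e-4 * (1.0 + abs(self.loglik))
        if stat < -tol:
            raise RuntimeError(
                f"restricted log-likelihood exceeds the full one by {-stat:.3g}: "
                "optimizer failure in the full model; refit with more restarts")
        stat = max(stat, 0.0)
        if mixture:
            p = 1.0 if stat == 0 else 0.5 * float(stats.chi2.sf(stat, df))
            note = "50:50 chi2(0):chi2(1) mixture"
        else:
            p = float(stats.chi2.sf(stat, df))
            note = ""
        return TestResult(float(stat), df, p, "LRT", label, note=note)

    # -- reliability interface ----------------------------------------
    def standardized_shares(self) -> dict:
        """Each component's share of total variance (sums to 1)."""
        from .reliability import standardized_shares
        return standardized_shares(self.theta_hat)

    def icc(self) -> float:
        from .reliability import icc
        return icc(self.theta_hat)

    def effective_error(self) -> float:
        from .reliability import effective_error
        return effective_error(self.model.design, self.theta_hat)

    def icc2(self) -> float:
        from .reliability import icc2
        return icc2(self.model.design, self.theta_hat)

    def reliability_report(self):
        from .reliability import reliability_report
        return reliability_report(self.model.design, self.theta_hat)

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        """Human-readable estimation summary table."""
        lines = []
        design = self.model.design
        lines.append("Intra-class effect decomposition (FIML)")
        lines.append("=" * 55)
        lines.append(f"Occasions: {design.n_occasions}   Persons: {self.n_persons}"
                     f"   Observed cells: {self.model.n_obs}")
        lines.append(f"Log-likelihood: {self.loglik:.4f}   "
                     f"Converged: {self.converged}")
        lines.append("-" * 55)
        lines.append(f"{'component':<14}{'estimate':>12}{'SE':>10}{'share':>9}")
        shares = self.standardized_shares()
        label = {"sigma_T2": "true_score", "sigma_E2": "residual"}
        for name in self._pmap.var_names:
            est = self.params[name]
            s = self.se.get(name, np.nan)
            se_txt = f"{s:.4f}" if np.isfinite(s) else "--"
            flag = " (at bound)" if name in self.boundary_flags else ""
            lines.append(f"{label.get(name, name):<14}{est:>12.4f}{se_txt:>10}"
                         f"{shares[name]:>9.3f}{flag}")
        for name in self._pmap.mean_names:
            lines.append(f"{name:<14}{self.params[name]:>12.4f}"
                         f"{self.se.get(name, np.nan):>10.4f}")
        lines.append("-" * 55)
        try:
            rel = self.reliability_report()
            lines.append(f"ICC = {rel.icc:.2f}   effective error = "
                         f"{rel.sigma_eff2:.4f}   ICC2 = {rel.icc2:.2f}")
        except ValueError:
            pass
        return "\n".join(lines)


# ---------------------------------------------------------------------
# multigroup models
# ---------------------------------------------------------------------

class MultigroupICEDModel:
    """Joint FIML model over several groups, with optional equality constraints.

    Each group has its own data and design (designs may differ, e.g.
    mirrored session layouts) and its own parameter set; components
    named in ``equal`` are constrained to a single value shared across
    all groups.  The joint log-likelihood is the sum of the group
    log-likelihoods.
    """

    def __init__(self, datasets: list[Dataset], designs: Design | list[Design],
                 per_occasion_means: bool = False):
        if isinstance(designs, Design):
            designs = [designs] * len(datasets)
        if len(designs) != len(datasets):
            raise ValueError("one design (or one per group) required")
        self.submodels = [ICEDModel(d, g, per_occasion_means)
                          for d, g in zip(datasets, designs)]
        names = {tuple(["sigma_T2", *m.design.facets, "sigma_E2"])
                 for m in self.submodels}
        if len(names) != 1:
            raise ValueError("all groups must share the same component names")
        self.component_names = list(next(iter(names)))

    @property
    def n_groups(self) -> int:
        return len(self.submodels)

    def fit(self, equal: list[str] | None = None, restarts: int = 5,
            seed: int = 0, tol: float = 1e-10) -> "MultigroupResults":
        """Maximise the joint likelihood.

        Parameters
        ----------
        equal
            Component names (e.g. ``["session"]``) constrained equal
            across groups.  Means and unlisted components stay
            group-specific.
        """
        equal_canon = []
        for c in (equal or []):
            if str(c).lower() == "mu":
                equal_canon.append("mu")
                continue
            equal_canon.append(canonical_component(self.submodels[0].design, c))
        for c in equal_canon:
            if c != "mu" and c not in self.component_names:
                raise KeyError(f"constraint names unknown parameter {c!r}")
        pmaps = [_ParameterMap(m.design, m.per_occasion_means)
                 for m in self.submodels]
        # free vector = shared params, then per-group params not shared
        shared = list(equal_canon)
        per_group = [[n for n in p.full_names if n not in shared] for p in pmaps]
        objectives = [m._objective(p) for m, p in zip(self.submodels, pmaps)]

        def split(x: np.ndarray) -> list[np.ndarray]:
            vals_shared = dict(zip(shared, x[:len(shared)]))
            out = []
            ofs = len(shared)
            for g, names in enumerate(per_group):
                vals = dict(zip(names, x[ofs:ofs + len(names)]))
                vals.update(vals_shared)
                out.append(pmaps[g].shrink(vals))
                ofs += len(names)
            return out

        def neg_loglik(x: np.ndarray) -> float:
            return sum(obj(xi) for obj, xi in zip(objectives, split(x)))

        starts = [m._start_values(p) for m, p in zip(self.submodels, pmaps)]
        base = np.concatenate([
            [np.mean([s[c] for s in starts]) for c in shared],
            *[np.array([s[n] for n in names])
              for s, names in zip(starts, per_group)]]) if shared else \
            np.concatenate([[s[n] for n in names]
                            for s, names in zip(starts, per_group)])
        bounds = [(None, None) if n == "mu" else (0.0, None) for n in shared]
        for p, names in zip(pmaps, per_group):
            for n in names:
                bounds.append((None, None) if n in p.mean_names else (0.0, None))

        rng = np.random.default_rng(seed)
        best = None
        for attempt in range(1 + max(0, restarts)):
            x0 = base.copy()
            if attempt > 0:
                pos = np.array([b[0] == 0.0 for b in bounds])
                x0 = np.where(pos, x0 * np.exp(0.7 * rng.standard_normal(len(x0))),
                              x0 + 0.2 * (1 + np.abs(x0)) * rng.standard_normal(len(x0)))
            res = optimize.minimize(neg_loglik, x0, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"ftol": tol, "maxiter": 1000})
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        assert best is not None
        group_free = split(best.x)
        group_results = []
        for m, p, xg in zip(self.submodels, pmaps, group_free):
            values = p.expand(xg)
            ll = -m._objective(p)(xg)
            boundary = {n for n in p.var_names if values[n] <= 1e-8}
            group_results.append(ICEDResults(
                model=m, pmap=p, values=values, loglik=ll, se={},
                converged=bool(best.success), boundary_flags=frozenset(boundary)))
        return MultigroupResults(self, group_results, -float(best.fun),
                                 n_free=len(best.x), equal=tuple(equal_canon),
                                 converged=bool(best.success))


class MultigroupResults:
    """Joint fit over groups: per-group results plus the joint likelihood."""

    def __init__(self, model: MultigroupICEDModel,
                 group_results: list[ICEDResults], loglik: float,
                 n_free: int, equal: tuple, converged: bool):
        self.model = model
        self.group_results = group_results
        self.loglik = float(loglik)
        self.df_model = int(n_free)
        self.equal = equal
        self.converged = converged


def interaction_lrt(free: MultigroupResults,
                    constrained: MultigroupResults) -> TestResult:
    """Chi-square test of cross-group equality of error components.

    Compares a multigroup fit with group-specific components against a
    fit in which the components of interest are constrained equal
    across groups (the no-interaction null, e.g. no session-by-day
    interaction in mirrored designs).  The difference in -2 log-
    likelihood is referred to chi2 with df equal to the number of
    constraints dropped.
    """
    df = free.df_model - constrained.df_model
    if df < 1:
        raise ValueError("models are not nested: the constrained fit must "
                         "have fewer free parameters")
    stat = -2.0 * (constrained.loglik - free.loglik)
    tol = 1e-4 * (1.0 + abs(free.loglik))
    if stat < -tol:
        raise RuntimeError(
            f"constrained log-likelihood exceeds the free one by {-stat:.3g}: "
            "optimizer failure; refit with more restarts")
    stat = max(stat, 0.0)
    label = "=".join(constrained.equal) if constrained.equal else "equality"
    return TestResult(float(stat), df, float(stats.chi2.sf(stat, df)),
                      "LRT", f"cross-group {label}")


# ---------------------------------------------------------------------
# functional conveniences mirroring the modelling surface
# ---------------------------------------------------------------------

def fiml_loglik(data: Dataset, design: Design, theta: VarianceComponents) -> float:
    """FIML log-likelihood of a dataset at fixed variance components."""
    return ICEDModel(data, design).loglik(theta)


def fit_fiml(data: Dataset, design: Design, **options) -> ICEDResults:
    """Fit the variance-component model by FIML; see :meth:`ICEDModel.fit`."""
    return ICEDModel(data, design).fit(**options)


def wald_test(fit: ICEDResults, component: str) -> TestResult:
    return fit.wald_test(component)


def lrt(data: Dataset, design: Design, component: str,
        mixture: bool = False, **fit_kwargs) -> TestResult:
    """LRT of one component against zero (full vs restricted refit)."""
    full = ICEDModel(data, design).fit(**fit_kwargs)
    return full.lrt(component, mixture=mixture,
                    **{k: v for k, v in fit_kwargs.items()
                       if k in ("restarts", "seed", "tol")})


def fit_multigroup(datasets: list[Dataset], design: Design | list[Design],
                   constraints: list[str] | None = None,
                   **options) -> MultigroupResults:
    """Joint multigroup fit with optional cross-group equality constraints."""
    return MultigroupICEDModel(datasets, design).fit(equal=constraints, **options)


def standardize(fit: ICEDResults) -> dict:
    """Standardized variance shares of a fitted model (sum to 1)."""
    return fit.standardized_shares()
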