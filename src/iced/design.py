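"""Repeated-measures designs and their model-implied covariance structure.

A :class:`Design` records which facet level (day, session, scanner, ...)
each measurement occasion belongs to.  Together with a
:class:`VarianceComponents` parameter set it implies a covariance matrix
for the observed occasions under a parallel measurement model: every
occasion loads with unit weight on a person-level true score, on one
random effect per facet level, and on an occasion-specific residual,

    Sigma = sigma_T^2 J + sum_f sigma_f^2 Z_f Z_f' + sigma_E^2 I,

where J is the all-ones matrix and Z_f the occasion-by-level membership
indicator for facet f.  All effects are orthogonal, so off-diagonal
entries accumulate exactly the variances of the components two occasions
share.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

RESERVED_FACET_NAMES = frozenset({"residual", "true_score"})

__all__ = [
    "Design",
    "VarianceComponents",
    "IdentifiabilityReport",
    "validate_design",
    "build_membership",
    "model_implied_covariance",
    "model_implied_correlation",
    "check_identifiability",
    "make_nested_design",
]


class DesignError(ValueError):
    """Invalid design specification."""


@dataclass(frozen=True)
class Design:
    """A repeated-measures design: occasions and their facet-level membership.

    Parameters
    ----------
    occasions
        Ordered occasion identifiers (e.g. scan labels).  Order is
        preserved everywhere; covariance matrices follow it.
    facets
        Ordered facet names, e.g. ``("day", "session")``.
    membership
        ``membership[facet][occasion]`` is the level of ``facet`` that
        ``occasion`` belongs to.  Levels are arbitrary hashables; their
        first-appearance order (over occasions) defines column order of
        membership matrices.
    """

    occasions: tuple
    facets: tuple
    membership: Mapping[str, Mapping]

    def __init__(self, occasions: Sequence, facets: Sequence[str] = (),
                 membership: Mapping[str, Mapping] | None = None):
        object.__setattr__(self, "occasions", tuple(occasions))
        object.__setattr__(self, "facets", tuple(facets))
        object.__setattr__(self, "membership",
                           {f: dict(m) for f, m in (membership or {}).items()})
        validate_design(self)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    def levels(self, facet: str) -> list:
        """Levels of a facet in order of first appearance over occasions."""
        if facet not in self.facets:
            raise DesignError(f"unknown facet {facet!r}")
        seen: list = []
        for occ in self.occasions:
            lev = self.membership[facet][occ]
            if lev not in seen:
                seen.append(lev)
        return seen

    def subset(self, occasions: Sequence) -> "Design":
        """Design restricted to a subset of occasions (same facets)."""
        membership = {f: {o: self.membership[f][o] for o in occasions}
                      for f in self.facets}
        return Design(occasions, self.facets, membership)


def validate_design(design: Design) -> Design:
    """Check design invariants; return the design unchanged if valid.

    Raises
    ------
    DesignError
        On duplicate occasions, fewer than two occasions, reserved or
        duplicate facet names, or an occasion lacking a facet level.
    """
    occ = design.occasions
    if len(occ) != len(set(occ)):
        raise DesignError("occasion identifiers must be unique")
    if len(occ) < 2:
        raise DesignError("a design needs at least 2 occasions")
    if len(design.facets) != len(set(design.facets)):
        raise DesignError("facet names must be unique")
    for f in design.facets:
        if f in RESERVED_FACET_NAMES:
            raise DesignError(f"facet name {f!r} is reserved")
        levels = design.membership.get(f)
        if levels is None:
            raise DesignError(f"no membership map for facet {f!r}")
        for o in occ:
            if o not in levels:
                raise DesignError(f"occasion {o!r} lacks a level for facet {f!r}")
    return design


@dataclass(frozen=True)
class VarianceComponents:
    """Variance parameters of the parallel model.

    Attributes
    ----------
    sigma_T2
        True-score (between-person) variance, squared measurement units.
    facet_variances
        One non-negative variance per facet, keyed by facet name
        (e.g. ``{"day": 1.0, "session": 0.5}``).
    sigma_E2
        Residual error variance.
    mu
        Common mean of all occasions (measurement units).
    """

    sigma_T2: float
    facet_variances: Mapping[str, float] = field(default_factory=dict)
    sigma_E2: float = 0.0
    mu: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "facet_variances", dict(self.facet_variances))
        for name, value in self.named_variances().items():
            if value < 0:
                raise ValueError(f"variance {name} must be >= 0, got {value}")

    def named_variances(self) -> dict:
        out = {"sigma_T2": float(self.sigma_T2)}
        out.update({f: float(v) for f, v in self.facet_variances.items()})
        out["sigma_E2"] = float(self.sigma_E2)
        return out

    @property
    def total_variance(self) -> float:
        """Model-implied variance of a single occasion."""
        return float(self.sigma_T2 + self.sigma_E2 + sum(self.facet_variances.values()))

    def matches(self, design: Design) -> bool:
        return set(self.facet_variances) == set(design.facets)


def _require_match(design: Design, theta: VarianceComponents) -> None:
    if not theta.matches(design):
        raise ValueError(
            f"components {sorted(theta.facet_variances)} do not match design "
            f"facets {sorted(design.facets)}")


def build_membership(design: Design, facet: str) -> np.ndarray:
    """Binary occasion-by-level indicator matrix Z_f for one facet.

    Each row has exactly one 1 (every occasion belongs to one level).
    Column order follows first appearance of levels over occasions.
    """
    levels = design.levels(facet)
    index = {lev: j for j, lev in enumerate(levels)}
    Z = np.zeros((design.n_occasions, len(levels)))
    for i, occ in enumerate(design.occasions):
        Z[i, index[design.membership[facet][occ]]] = 1.0
    return Z


def model_implied_covariance(design: Design, theta: VarianceComponents) -> np.ndarray:
    """Model-implied occasion-by-occasion covariance matrix.

    ``Sigma = sigma_T^2 J + sum_f sigma_f^2 Z_f Z_f' + sigma_E^2 I``.
    Diagonal entries equal the total variance; an off-diagonal entry is
    the true-score variance plus the variances of every facet level the
    two occasions share.
    """
    _require_match(design, theta)
    n = design.n_occasions
    sigma = np.full((n, n), float(theta.sigma_T2))
    for f in design.facets:
        Z = build_membership(design, f)
        sigma += theta.facet_variances[f] * (Z @ Z.T)
    sigma += theta.sigma_E2 * np.eye(n)
    return sigma


def error_covariance(design: Design, theta: VarianceComponents) -> np.ndarray:
    """Covariance of the error part only (true-score variance removed)."""
    _require_match(design, theta)
    n = design.n_occasions
    sigma = np.zeros((n, n))
    for f in design.facets:
        Z = build_membership(design, f)
        sigma += theta.facet_variances[f] * (Z @ Z.T)
    sigma += theta.sigma_E2 * np.eye(n)
    return sigma


def model_implied_correlation(design: Design, theta: VarianceComponents,
                              i, j) -> float:
    """Model-implied correlation between two distinct occasions.

    Under the parallel model all occasions share the same total
    variance, so this is ``cov(i, j) / total_variance``.  For two
    occasions in the same session it reproduces the test-retest
    correlation (sigma_T^2 + shared facet variances) / total variance.
    """
    if i == j:
        raise ValueError("occasions must be distinct")
    total = theta.total_variance
    if total <= 0:
        raise ValueError("total variance must be > 0")
    sigma = model_implied_covariance(design, theta)
    ii = design.occasions.index(i)
    jj = design.occasions.index(j)
    return float(sigma[ii, jj] / total)


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Whether all variance components are separately estimable.

    ``identified`` is true iff the Jacobian of the unique covariance
    entries with respect to the variance parameters has full column
    rank.  ``confounded_sets`` lists groups of parameter names whose
    Jacobian columns are linearly dependent (inseparable from one
    another in this design).
    """

    identified: bool
    jacobian_rank: int
    n_parameters: int
    parameter_names: tuple
    confounded_sets: tuple

    def __str__(self) -> str:
        status = "identified" if self.identified else "NOT identified"
        msg = (f"Design is {status}: Jacobian rank {self.jacobian_rank} "
               f"of {self.n_parameters} variance parameters.")
        if self.confounded_sets:
            groups = "; ".join("{" + ", ".join(g) + "}" for g in self.confounded_sets)
            msg += f" Confounded parameter sets: {groups}."
        return msg


def _vech(mat: np.ndarray) -> np.ndarray:
    idx = np.triu_indices(mat.shape[0])
    return mat[idx]


def check_identifiability(design: Design, n_points: int = 3,
                          seed: int = 20180702, rtol: float = 1e-8) -> IdentifiabilityReport:
    """Numerically check whether all variance components are identified.

    The covariance matrix is linear in the variance parameters, but the
    check follows the generic recipe: evaluate the Jacobian of the
    half-vectorised covariance with respect to (sigma_T^2, facet
    variances, sigma_E^2) at several random strictly positive parameter
    points and require full column rank (singular values above ``rtol``
    times the largest) at every point.  Rank deficiency is generic, so
    multiple points guard against accidental degeneracy at one point.
    """
    validate_design(design)
    names = ["sigma_T2"] + list(design.facets) + ["sigma_E2"]
    n_par = len(names)
    rng = np.random.default_rng(seed)

    def jacobian_at(point: np.ndarray) -> np.ndarray:
        # central differences of vech(Sigma) w.r.t. each variance
        cols = []
        h = 1e-6
        for k in range(n_par):
            lo, hi = point.copy(), point.copy()
            lo[k] -= h
            hi[k] += h
            cols.append((_vech(_sigma_from_vector(design, hi))
                         - _vech(_sigma_from_vector(design, lo))) / (2 * h))
        return np.column_stack(cols)

    min_rank = n_par
    worst_jac = None
    for _ in range(max(1, n_points)):
        point = rng.uniform(0.5, 2.0, size=n_par)
        J = jacobian_at(point)
        s = np.linalg.svd(J, compute_uv=False)
        rank = int(np.sum(s > rtol * s[0]))
        if rank < min_rank:
            min_rank = rank
            worst_jac = J
    identified = min_rank == n_par

    confounded: list[tuple] = []
    if not identified and worst_jac is not None:
        # parameters sharing support in any null-space vector are inseparable
        _, s, vt = np.linalg.svd(worst_jac)
        null_vecs = vt[min_rank:]
        groups: list[set] = []
        for v in null_vecs:
            involved = {names[k] for k in np.nonzero(np.abs(v) > 1e-6)[0]}
            merged = False
            for g in groups:
                if g & involved:
                    g |= involved
                    merged = True
                    break
            if not merged:
                groups.append(set(involved))
        confounded = [tuple(sorted(g)) for g in groups]

    return IdentifiabilityReport(
        identified=identified,
        jacobian_rank=min_rank,
        n_parameters=n_par,
        parameter_names=tuple(names),
        confounded_sets=tuple(confounded),
    )


def _sigma_from_vector(design: Design, vec: np.ndarray) -> np.ndarray:
    theta = VarianceComponents(
        sigma_T2=vec[0],
        facet_variances={f: vec[1 + k] for k, f in enumerate(design.facets)},
        sigma_E2=vec[-1],
    )
    return model_implied_covariance(design, theta)


def make_nested_design(n_days: int = 1, sessions_per_day: int = 1,
                       runs_per_session: int = 1,
                       facets: Sequence[str] = ("day", "session")) -> Design:
    """Build a nested day/session/run design.

    Occasions are labelled ``scan1, scan2, ...`` in acquisition order:
    days outermost, sessions within day, runs within session.  With
    ``facets=("session",)`` the day facet is omitted (single-day
    designs such as two back-to-back runs plus one repositioned run:
    ``make_nested_design(sessions_per_day=2, runs_per_session=...)``).
    """
    occasions = []
    membership: dict = {f: {} for f in facets}
    i = 0
    for d in range(n_days):
        for s in range(sessions_per_day):
            for _ in range(runs_per_session):
                i += 1
                occ = f"scan{i}"
                occasions.append(occ)
                if "day" in membership:
                    membership["day"][occ] = f"d{d + 1}"
                if "session" in membership:
                    membership["session"][occ] = f"d{d + 1}s{s + 1}"
    return Design(occasions, facets, membership)


def two_day_design() -> Design:
    """The minimal 4-scan design separating day and session variance.

    Two back-to-back scans in a single session on day 1, then two scans
    in two separate sessions on day 2.  All of true-score, day, session
    and residual variance are identified.
    """
    occasions = ("scan1", "scan2", "scan3", "scan4")
    membership = {
        "day": {"scan1": "d1", "scan2": "d1", "scan3": "d2", "scan4": "d2"},
        "session": {"scan1": "s1", "scan2": "s1", "scan3": "s2", "scan4": "s3"},
    }
    return Design(occasions, ("day", "session"), membership)


def three_scan_design() -> Design:
    """Three scans in one day: two back-to-back, one after repositioning.

    Separates session-specific variance (repositioning) from true-score
    and residual variance; day variance is not identifiable and is
    absorbed into the true score.
    """
    occasions = ("scan1", "scan2", "scan3")
    membership = {"session": {"scan1": "s1", "scan2": "s1", "scan3": "s2"}}
    return Design(occasions, ("session",), membership)
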