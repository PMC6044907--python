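"""Readers, writers, configuration and the end-to-end analysis runner.

File formats
------------
* Design config: YAML with keys ``occasions`` (list) and ``facets``
  (mapping facet -> mapping occasion -> level).
* Wide CSV: header = person-id column plus occasion columns; optional
  ``group`` column; empty cell or ``NA`` = missing.
* Long CSV: columns ``person, occasion, value`` and optionally ``group``.
* Analysis report: JSON (full double precision) with a shipped schema,
  plus a human-readable text rendering.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .data import Dataset
from .design import Design, check_identifiability, validate_design
from .model import ICEDModel, canonical_component

__all__ = ["read_design", "write_design", "read_wide", "write_wide",
           "read_long", "write_long", "AnalysisConfig", "run_analysis",
           "AnalysisReport"]

MISSING_TOKENS = ("", "NA", "NaN", "nan")


# -- design configs ---------------------------------------------------

def read_design(path) -> Design:
    """Load a design from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "occasions" not in raw:
        raise ValueError(f"{path}: design config must define 'occasions'")
    occasions = [str(o) for o in raw["occasions"]]
    facets_raw = raw.get("facets", {}) or {}
    facets = list(facets_raw)
    membership = {f: {str(o): str(l) for o, l in mapping.items()}
                  for f, mapping in facets_raw.items()}
    return Design(occasions, facets, membership)


def write_design(design: Design, path) -> None:
    doc = {"occasions": list(design.occasions),
           "facets": {f: {o: design.membership[f][o] for o in design.occasions}
                      for f in design.facets}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_example_design(name: str) -> Design:
    """Load one of the shipped example designs by file stem.

    Available: ``two_day_four_scan`` (2 days x 3 sessions x 4 scans)
    and ``single_day_three_scan`` (two back-to-back scans + one scan
    after repositioning).
    """
    root = Path(__file__).parent / "designs"
    path = root / f"{name}.yaml"
    if not path.exists():
        options = sorted(p.stem for p in root.glob("*.yaml"))
        raise FileNotFoundError(f"no example design {name!r}; options: {options}")
    return read_design(path)


# -- tabular data -----------------------------------------------------

def read_wide(path, person_col: str | None = None) -> Dataset:
    """Read a wide CSV (first column person id unless ``person_col`` given)."""
    frame = pd.read_csv(path, na_values=list(MISSING_TOKENS),
                        keep_default_na=False, dtype={0: str} if person_col is None else None)
    if person_col is None:
        person_col = frame.columns[0]
    frame[person_col] = frame[person_col].astype(str)
    if frame[person_col].duplicated().any():
        dup = frame[person_col][frame[person_col].duplicated()].tolist()
        raise ValueError(f"duplicate person ids: {dup}")
    return Dataset.from_wide(frame, person_col=person_col)


def write_wide(data: Dataset, path) -> None:
    """Write wide CSV; missing cells become empty fields."""
    out = data.values.copy()
    if data.group is not None:
        out["group"] = data.group
    out.index.name = "person"
    out.to_csv(path, na_rep="")


def read_long(path) -> Dataset:
    """Read long CSV with columns person, occasion, value[, group]."""
    frame = pd.read_csv(path, na_values=list(MISSING_TOKENS),
                        keep_default_na=False)
    required = {"person", "occasion", "value"}
    if not required <= set(frame.columns):
        raise ValueError(f"long format needs columns {sorted(required)}, "
                         f"got {list(frame.columns)}")
    frame["person"] = frame["person"].astype(str)
    frame["occasion"] = frame["occasion"].astype(str)
    frame["value"] = pd.to_numeric(frame["value"], errors="raise")
    return Dataset.from_long(frame)


def write_long(data: Dataset, path) -> None:
    long = (data.values.rename_axis("person").reset_index()
            .melt(id_vars="person", var_name="occasion", value_name="value")
            .dropna(subset=["value"]))
    long.to_csv(path, index=False)


# -- analysis configuration and report --------------------------------

class AnalysisConfig(BaseModel):
    """Everything needed to run one reliability analysis end to end."""

    design: str
    data: str
    format: Literal["wide", "long"] = "wide"
    tests: list[str] = Field(default_factory=list)
    mixture_lrt: bool = False
    per_occasion_means: bool = False
    seed: int = 0
    restarts: int = 5

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class TestEntry(BaseModel):
    component: str
    kind: Literal["LRT", "Wald"]
    statistic: float
    df: int
    p_value: float
    note: str = ""


class AnalysisReport(BaseModel):
    """Schema of the JSON analysis report."""

    estimates: dict[str, float]
    standard_errors: dict[str, Optional[float]]
    shares: dict[str, float]
    icc: float
    sigma_eff2: float
    icc2: float
    loglik: float
    converged: bool
    boundary: list[str]
    n_persons: int
    n_occasions: int
    tests: list[TestEntry]
    seed: int


def run_analysis(config: AnalysisConfig, log=None) -> AnalysisReport:
    """Run the full pipeline: load, check identifiability, fit, test, report.

    Deterministic given the config (seed included).  Refuses
    unidentified designs with the identifiability report in the error
    message.  A request to LR-test the residual component is rejected
    with a pointer to the Wald test, which remains available because it
    needs no restricted refit.
    """
    def say(msg):
        if log is not None:
            log(msg)

    design = read_design(config.design)
    validate_design(design)
    ident = check_identifiability(design)
    if not ident.identified:
        raise ValueError(f"refusing to fit an unidentified design. {ident}")
    say(f"design ok: {design.n_occasions} occasions, facets {design.facets}")

    reader = read_wide if config.format == "wide" else read_long
    data = reader(config.data)
    say(f"loaded {data}")

    model = ICEDModel(data, design, per_occasion_means=config.per_occasion_means)
    fit = model.fit(restarts=config.restarts, seed=config.seed)
    say(f"fit converged={fit.converged} loglik={fit.loglik:.4f} "
        f"boundary={sorted(fit.boundary_flags)}")

    tests: list[TestEntry] = []
    for component in config.tests:
        name = canonical_component(design, component)
        if name == "sigma_E2":
            raise ValueError(
                "an LRT on the residual component is not estimable (its null "
                "model is singular); request a Wald test via wald_test/"
                "the residual Wald entry, which this report always includes")
        res = fit.lrt(component, mixture=config.mixture_lrt,
                      restarts=config.restarts, seed=config.seed)
        tests.append(TestEntry(component=res.component, kind=res.kind,
                               statistic=res.statistic, df=res.df,
                               p_value=res.p_value, note=res.note))
    # residual tested by Wald (no estimable null model exists for it)
    try:
        wald = fit.wald_test("residual")
        tests.append(TestEntry(component=wald.component, kind=wald.kind,
                               statistic=wald.statistic, df=wald.df,
                               p_value=wald.p_value, note=wald.note))
    except (RuntimeError, ValueError) as exc:
        say(f"residual Wald test unavailable: {exc}")

    rel = fit.reliability_report()
    se = {k: (float(v) if np.isfinite(v) else None) for k, v in fit.se.items()}
    return AnalysisReport(
        estimates={k: float(v) for k, v in fit.params.items()},
        standard_errors=se,
        shares=dict(rel.shares),
        icc=rel.icc, sigma_eff2=rel.sigma_eff2, icc2=rel.icc2,
        loglik=fit.loglik, converged=fit.converged,
        boundary=sorted(fit.boundary_flags),
        n_persons=fit.n_persons, n_occasions=design.n_occasions,
        tests=tests, seed=config.seed,
    )


def report_to_json(report: AnalysisReport) -> str:
    """Serialize at full double precision, stable key order."""
    return json.dumps(report.model_dump(), indent=2, sort_keys=True)


def report_to_text(report: AnalysisReport) -> str:
    """Two-decimal human-readable rendering of the report."""
    lines = ["Reliability analysis report", "=" * 40]
    lines.append(f"persons: {report.n_persons}  occasions: {report.n_occasions}")
    lines.append(f"log-likelihood: {report.loglik:.4f}  converged: {report.converged}")
    lines.append("-" * 40)
    for name, est in report.estimates.items():
        se = report.standard_errors.get(name)
        se_txt = f" (SE {se:.4f})" if se is not None else ""
        share = report.shares.get(name)
        share_txt = f"  share {100 * share:.0f}%" if share is not None else ""
        flag = "  [at bound]" if name in report.boundary else ""
        lines.append(f"{name:<12} {est:10.4f}{se_txt}{share_txt}{flag}")
    lines.append("-" * 40)
    lines.append(f"ICC  = {report.icc:.2f}")
    lines.append(f"effective error = {report.sigma_eff2:.4f}")
    lines.append(f"ICC2 = {report.icc2:.2f}")
    for t in report.tests:
        lines.append(f"{t.kind} {t.component}: stat={t.statistic:.3f} "
                     f"df={t.df} p={t.p_value:.4f}"
                     + (f" ({t.note})" if t.note else ""))
    return "\n".join(lines)
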