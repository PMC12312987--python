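"""End-to-end study orchestration over a federation of cohort nodes.

Stages mirror the study protocol: flowchart accounting (inclusion and
transfer censoring), univariate descriptives with and without local DP,
bivariate screening of confounders against the inclusion period,
federated linear regression of first-line duration on period, and a
center-stratified Cox model of progression at 24 months.  Output is one
machine-readable report dict (JSON-serializable) plus a Markdown
rendering.

Reporting conventions: without DP the released percentile grid is
{5, 25, 50, 75, 95} and minima/maxima are withheld as disclosive; with
DP, min/max and the median become releasable because the noise itself
protects them.  Every DP cell carries its epsilon annotation, and the
privacy ledger snapshot closes the report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable, StudyConfig, load_cohort
from .federation import (
    DisclosurePolicy,
    Federation,
    MaskedResultError,
    Node,
    QuerySpec,
)
from .inference import dp_t_test, screen_confounders, select_test, student_t, test_association, GroupSummary
from .models import DesignSpec, ModelFit, fed_cox, fed_ols, significance_by_ci

__all__ = [
    "RunConfig",
    "StageError",
    "build_federation",
    "run_flowchart",
    "run_univariate",
    "run_bivariate",
    "run_full_study",
    "render_markdown",
]

CATEGORICAL_VARS = ("gender", "age_class", "bmi_class", "treatment_category")
QUANTITATIVE_VARS = ("firstline_duration_days", "creatinemia")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    node_paths: tuple[str, ...] = ()
    study: StudyConfig = field(default_factory=StudyConfig)
    dp: bool = False
    noise_free: bool = False  # test-only: DP plumbing with zeroed noise
    yates: bool = True
    seed: int = 0
    out_dir: str | None = None
    strict_disclosure: bool = False

    def __post_init__(self) -> None:
        if self.dp and self.seed is None:
            raise ValueError("a seed is required when DP is on")


def build_federation(
    tables: Sequence[CohortTable], config: RunConfig
) -> Federation:
    policy = DisclosurePolicy(
        min_cell_count=config.study.disclosure_min_cell,
        min_subset_n=config.study.disclosure_min_cell,
        strict=config.strict_disclosure,
    )
    nodes = [Node(t.center, t) for t in tables]
    fed = Federation(nodes, policy, root_seed=config.seed, noise_free=config.noise_free)
    # annotate each node with the derived progression outcome so it can be
    # queried like any categorical variable
    for nd in fed.nodes:
        oc = nd.table.outcomes()
        nd.table.df["progression"] = np.where(oc["event"] == 1, "Yes", "No")
    return fed


# ---------------------------------------------------------------------------
# stages


def run_flowchart(fed: Federation, study: StudyConfig) -> dict:
    """Inclusion / censoring accounting and the two analysis sets.

    The progression analysis keeps every included patient (transfers are
    censored at the transfer date); the duration analysis excludes
    transferred patients entirely.
    """
    acc: dict = {"periods": {}}
    for period in ("before", "after"):
        included = progressed = transferred = 0
        for nd in fed.nodes:
            oc = nd.table.outcomes()
            sel = oc["period"] == period
            included += int(sel.sum())
            progressed += int((sel & (oc["event"] == 1)).sum())
            transferred += int((sel & (oc["censor_reason"] == "transfer")).sum())
        acc["periods"][period] = {
            "included": included,
            "progressed": progressed,
            "progression_free": included - progressed - transferred,
            "transferred": transferred,
            "duration_analysis_n": included - transferred,
        }
    acc["warnings"] = [
        f"period {p}: duration analysis set is empty"
        for p, d in acc["periods"].items()
        if d["duration_analysis_n"] == 0
    ]
    return acc


def run_univariate(fed: Federation, study: StudyConfig, dp: bool) -> dict:
    """Pooled descriptives per variable, optionally under local DP.

    Without DP: mean, SD and the {5,25,50,75,95} percentile grid; no
    min/max (disclosive).  With DP: noisy mean, SD, median, min and max,
    each released at epsilon_univariate.
    """
    eps = study.epsilon_univariate
    out: dict = {"dp": dp, "epsilon": eps if dp else None, "variables": {}}
    mode = "local" if dp else "none"
    e = eps if dp else None
    for var in QUANTITATIVE_VARS:
        try:
            cell: dict = {
                "mean": fed.run_query(QuerySpec(var, "mean", dp=mode, epsilon=e)).value,
                "sd": fed.run_query(QuerySpec(var, "sd", dp=mode, epsilon=e)).value,
            }
            if dp:
                cell["median"] = fed.run_query(
                    QuerySpec(var, "quantile", q=0.5, dp=mode, epsilon=e)
                ).value
                cell["min"] = fed.run_query(QuerySpec(var, "min", dp=mode, epsilon=e)).value
                cell["max"] = fed.run_query(QuerySpec(var, "max", dp=mode, epsilon=e)).value
            else:
                cell["percentiles"] = fed.run_query(QuerySpec(var, "percentiles")).value
        except MaskedResultError:
            cell = {"masked": True}
        out["variables"][var] = cell
    for var in CATEGORICAL_VARS + ("progression",):
        try:
            counts = fed.run_query(QuerySpec(var, "histogram", dp=mode, epsilon=e)).value
            total = int(counts.sum())
            out["variables"][var] = {
                "counts": {k: int(v) for k, v in counts.items()},
                "percent": {
                    k: round(100.0 * v / total, 1) if total else 0.0 for k, v in counts.items()
                },
            }
        except MaskedResultError:
            out["variables"][var] = {"masked": True}
    return out


def _period_table(fed: Federation, var: str, dp: bool, eps: float | None) -> pd.DataFrame:
    mode = "local" if dp else "none"
    res = fed.run_query(
        QuerySpec(var, "histogram", group_by="period", dp=mode, epsilon=eps if dp else None)
    )
    return res.value


def run_bivariate(fed: Federation, study: StudyConfig, dp: bool, yates: bool = True) -> dict:
    """Per-variable period comparison: occurrence tables + test p-values.

    Categorical variables get a pooled category x period table and the
    chi-square/Fisher selection rule; quantitative variables get the
    pooled-variance t-test (its DP version spends epsilon_ttest per
    node).  Organization (center membership) is descriptive public
    metadata and is never noised.
    """
    eps = study.epsilon_univariate
    out: dict = {"dp": dp, "variables": {}, "p_values": {}}

    # organization: per-node per-period counts (public metadata)
    org = pd.DataFrame(
        {
            period: {
                nd.id: int((nd.table.df["period"] == period).sum()) for nd in fed.nodes
            }
            for period in ("before", "after")
        }
    )
    res = test_association(org, yates=yates)
    out["variables"]["organization"] = {
        "table": org.to_dict(),
        "test": res.test,
        "p": res.p_value,
    }
    out["p_values"]["organization"] = res.p_value

    for var in CATEGORICAL_VARS + ("progression",):
        try:
            tab = _period_table(fed, var, dp, eps)
        except MaskedResultError:
            out["variables"][var] = {"masked": True}
            continue
        # drop all-zero rows (a level absent in both periods has no
        # information and breaks the chi-square margin requirement)
        kept = tab.loc[tab.sum(axis=1) > 0]
        res = test_association(kept, yates=yates, seed=fed.root_seed)
        out["variables"][var] = {
            "table": tab.to_dict(),
            "test": res.test,
            "p": res.p_value,
            "epsilon": eps if dp else None,
        }
        out["p_values"][var] = res.p_value

    for var in QUANTITATIVE_VARS:
        if dp:
            res = dp_t_test(
                fed.nodes,
                var,
                "period",
                study.epsilon_ttest,
                root_seed=fed.root_seed,
                noise_free=fed.noise_free,
            )
            cell = {"test": "t (dp)", "p": res.p_value, "epsilon": study.epsilon_ttest}
        else:
            groups = []
            for period in ("before", "after"):
                resm = fed.run_query(QuerySpec(var, "mean", filter={"period": period}))
                s = fed.run_query(QuerySpec(var, "sd", filter={"period": period})).value
                nn = int(sum(msg.n for msg in resm.messages if msg.status == "ok"))
                groups.append(GroupSummary(nn, resm.value, s))
            res = student_t(*groups)
            cell = {
                "test": "t",
                "p": res.p_value,
                "by_period": {
                    p: {"n": g.n, "mean": g.mean, "sd": g.sd}
                    for p, g in zip(("before", "after"), groups)
                },
            }
        if res.degenerate:
            cell["degenerate"] = True
        out["variables"][var] = {**out["variables"].get(var, {}), **cell}
        out["p_values"][var] = res.p_value
    return out


def run_full_study(
    tables: Sequence[CohortTable], config: RunConfig
) -> dict:
    """Flowchart -> univariate -> bivariate -> screening -> models -> report."""
    report: dict = {"config": {"dp": config.dp, "seed": config.seed, "yates": config.yates}}
    fed = build_federation(tables, config)
    study = config.study

    def stage(name, fn, *args, **kwargs):
        try:
            report[name] = fn(*args, **kwargs)
            return report[name]
        except Exception as exc:  # the stage name travels with the failure
            report[name] = {"error": str(exc)}
            raise StageError(name, exc) from exc

    stage("flowchart", run_flowchart, fed, study)
    stage("univariate", run_univariate, fed, study, config.dp)
    bay = stage("bivariate", run_bivariate, fed, study, config.dp, config.yates)

    covariable_p = {
        k: v
        for k, v in bay["p_values"].items()
        if k not in ("progression", "firstline_duration_days")
    }
    selected = sorted(screen_confounders(covariable_p, study.screening_alpha))
    report["selected_confounders"] = selected

    # duration model on the duration analysis set (transfers excluded)
    dur_tables = [t.subset(t.df["transfer_day"].isna()) for t in (nd.table for nd in fed.nodes)]
    dur_design = DesignSpec("firstline_duration_days", tuple(["period"] + selected))
    cox_design = DesignSpec("progression", tuple(["period"] + selected))

    def fit_models():
        ols = fed_ols([Node(t.center, t) for t in dur_tables], dur_design)
        cox = fed_cox(fed.nodes, DesignSpec("time_days", cox_design.covariates))
        return ols, cox

    try:
        ols, cox = fit_models()
    except Exception as exc:
        report["models"] = {"error": str(exc)}
        raise StageError("models", exc) from exc

    report["models"] = {
        "ols": _fit_dict(ols),
        "cox": _fit_dict(cox, hazard=True),
    }
    report["significance"] = {
        "ols": {k: bool(v) for k, v in significance_by_ci(ols).items()},
        "cox": {k: bool(v) for k, v in significance_by_ci(cox).items()},
    }
    report["ledger"] = {
        "per_node": {nd.id: nd.ledger.total(nd.id) for nd in fed.nodes},
        "entries": [e for nd in fed.nodes for e in nd.ledger.entries],
    }
    return report


def _fit_dict(fit: ModelFit, hazard: bool = False) -> dict:
    d = {
        "kind": fit.kind,
        "n": fit.n,
        "converged": fit.converged,
        "iterations": fit.iterations,
        "coefficients": {
            name: {
                "estimate": float(fit.params[name]),
                "se": float(fit.se[name]),
                "ci_lower": float(fit.conf_int.loc[name, "lower"]),
                "ci_upper": float(fit.conf_int.loc[name, "upper"]),
            }
            for name in fit.params.index
        },
    }
    if hazard:
        hr = fit.hazard_ratios()
        d["hazard_ratios"] = {
            name: {
                "HR": float(hr.loc[name, "HR"]),
                "ci_lower": float(hr.loc[name, "lower"]),
                "ci_upper": float(hr.loc[name, "upper"]),
            }
            for name in hr.index
        }
    return d


def format_p(p: float) -> str:
    """Two decimals, '<.001' below a thousandth (report layer only)."""
    if p < 0.001:
        return "<.001"
    return f"{p:.2f}".lstrip("0") or ".00"


def render_markdown(report: dict) -> str:
    lines = ["# Federated study report", ""]
    fc = report.get("flowchart", {})
    if "periods" in fc:
        lines.append("## Flowchart")
        for period, d in fc["periods"].items():
            lines.append(
                f"- {period}: {d['included']} included, {d['progressed']} progressed, "
                f"{d['transferred']} transferred (censored), "
                f"duration analysis n={d['duration_analysis_n']}"
            )
        lines.append("")
    bay = report.get("bivariate", {})
    if "variables" in bay:
        lines.append("## Bivariate analysis")
        lines.append("| Variable | Test | P value |")
        lines.append("|---|---|---|")
        for var, cell in bay["variables"].items():
            if cell.get("masked"):
                lines.append(f"| {var} | — | masked |")
            else:
                lines.append(f"| {var} | {cell.get('test','')} | {format_p(cell['p'])} |")
        lines.append("")
    if "selected_confounders" in report:
        sel = ", ".join(report["selected_confounders"]) or "(none)"
        lines.append(f"Selected confounders: {sel}")
        lines.append("")
    models = report.get("models", {})
    for kind, title in (("ols", "Linear regression (duration ~ period)"),
                        ("cox", "Stratified Cox (progression ~ period)")):
        fit = models.get(kind)
        if not fit or "coefficients" not in fit:
            continue
        lines.append(f"## {title}")
        if kind == "cox" and "hazard_ratios" in fit:
            for name, d in fit["hazard_ratios"].items():
                lines.append(
                    f"- {name}: HR {d['HR']:.2f} (95% CI {d['ci_lower']:.2f}-{d['ci_upper']:.2f})"
                )
        else:
            for name, d in fit["coefficients"].items():
                lines.append(
                    f"- {name}: {d['estimate']:.2f} "
                    f"(95% CI {d['ci_lower']:.2f} to {d['ci_upper']:.2f})"
                )
        lines.append("")
    ledger = report.get("ledger", {})
    if ledger:
        lines.append("## Privacy budget spent (per node)")
        for node, tot in ledger.get("per_node", {}).items():
            lines.append(f"- {node}: epsilon = {tot:g}")
        lines.append("")
    return "\n".join(lines)


def write_report(report: dict, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / "report.json"
    mpath = out / "report.md"
    jpath.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    mpath.write_text(render_markdown(report))
    return jpath, mpath
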