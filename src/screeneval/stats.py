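"""Summary statistics and report tables for model benchmarks.

Per-template enrichment distributions (median/max/min and quartiles with
linear-interpolation quantiles, matching common boxplot semantics), ordinary
least-squares regression with Pearson's correlation coefficient, and
deterministic CSV-ready report tables keyed by template.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DegenerateInputError",
    "ReportJoinError",
    "TemplateSummary",
    "RegressionResult",
    "summarize_template",
    "regress",
    "build_report",
]


class DegenerateInputError(ValueError):
    """Empty values or zero-variance regressor."""


class ReportJoinError(ValueError):
    """Report inputs reference inconsistent template ids."""


@dataclass(frozen=True)
class TemplateSummary:
    template_id: str
    n_models: int
    median: float
    maximum: float
    minimum: float
    q25: float
    q75: float
    ensemble_alogauc: float | None = None


@dataclass(frozen=True)
class RegressionResult:
    name: str
    slope: float
    intercept: float
    pearson_r: float
    n: int


def summarize_template(
    template_id: str,
    values: Sequence[float],
    ensemble_alogauc: float | None = None,
) -> TemplateSummary:
    """Order statistics of one template's per-model aLogAUC values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise DegenerateInputError(
            f"template {template_id!r}: need >=1 finite value"
        )
    q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return TemplateSummary(
        template_id=template_id,
        n_models=int(arr.size),
        median=float(med),
        maximum=float(arr.max()),
        minimum=float(arr.min()),
        q25=float(q25),
        q75=float(q75),
        ensemble_alogauc=ensemble_alogauc,
    )


def regress(x: Sequence[float], y: Sequence[float], name: str = "") -> RegressionResult:
    """OLS fit y = slope*x + intercept plus Pearson's r."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size or xa.size < 2:
        raise DegenerateInputError("regression needs equal-length inputs, n >= 2")
    if np.ptp(xa) == 0:
        raise DegenerateInputError("regressor has zero variance")
    fit = sps.linregress(xa, ya)
    return RegressionResult(
        name=name,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n=int(xa.size),
    )


def build_report(
    summaries: Sequence[TemplateSummary],
    regressions: Sequence[RegressionResult] = (),
    rmsd_rows: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble deterministic report tables keyed by template.

    ``rmsd_rows`` (optional) must carry a ``template_id`` column whose ids
    all appear among the summaries; offenders raise a join error.  Returns
    a dict of DataFrames: always ``enrichment``, plus ``regressions`` and
    ``rmsd``/``combined`` when supplied.  Rows are sorted so identical
    inputs serialize byte-identically.
    """
    if not summaries:
        raise DegenerateInputError("report needs >=1 template summary")
    enr = pd.DataFrame(
        [
            {
                "template_id": s.template_id,
                "n_models": s.n_models,
                "median_alogauc": s.median,
                "max_alogauc": s.maximum,
                "min_alogauc": s.minimum,
                "q25_alogauc": s.q25,
                "q75_alogauc": s.q75,
                "ensemble_alogauc": s.ensemble_alogauc,
            }
            for s in summaries
        ]
    ).sort_values("template_id", ignore_index=True)
    report: dict[str, pd.DataFrame] = {"enrichment": enr}

    if regressions:
        report["regressions"] = pd.DataFrame(
            [
                {
                    "name": r.name,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "pearson_r": r.pearson_r,
                    "n": r.n,
                }
                for r in regressions
            ]
        ).sort_values("name", ignore_index=True)

    if rmsd_rows is not None:
        if "template_id" not in rmsd_rows.columns:
            raise ReportJoinError("rmsd table lacks a template_id column")
        known = set(enr["template_id"])
        offenders = sorted(set(rmsd_rows["template_id"]) - known)
        if offenders:
            raise ReportJoinError(
                f"rmsd rows reference unknown template ids: {offenders}"
            )
        rmsd_sorted = rmsd_rows.sort_values(
            list(rmsd_rows.columns), ignore_index=True
        )
        report["rmsd"] = rmsd_sorted
        report["combined"] = enr.merge(
            rmsd_sorted.groupby("template_id", as_index=False).mean(numeric_only=True),
            on="template_id",
            how="left",
        )
    return report
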