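"""Bootstrap mean comparisons, regression screens and cohort summaries.

All mean comparisons use percentile bootstrap tests (1000 resamples by
default) rather than parametric t-tests; regressions against the 16
per-subject covariates are ordinary least squares with an intercept,
screened one predictor at a time (no multiple-testing correction by
default, with an optional Benjamini-Hochberg flag) and as a full
multivariate fit.  A reproduction runner recomputes the published cohort
aggregates from supplementary-style per-patient tables and reports
pass/fail against the printed values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .synthetic import COVARIATE_NAMES

__all__ = [
    "BootstrapResult",
    "RegressionReport",
    "bootstrap_mean_diff",
    "univariate_screen",
    "multivariate_fit",
    "cohort_summary",
    "reproduce_supplementary",
    "REFERENCE_AGGREGATES",
]

logger = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    estimate: float
    ci: tuple[float, float]
    p_two_sided: float
    n_boot: int
    seed: int | None
    paired: bool


@dataclass
class RegressionReport:
    response: str
    predictors: list[str]
    coefficients: dict[str, float]
    f_stat: float
    df: tuple[int, int]
    r_squared: float
    p_overall: float
    p_per_coef: dict[str, float]
    n: int


def bootstrap_mean_diff(
    x,
    y,
    paired: bool = False,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> BootstrapResult:
    """Percentile bootstrap test of mean(x) − mean(y).

    Pairs (or each group independently when unpaired) are resampled with
    replacement ``n_boot`` times; the two-sided p-value is
    ``2·min(P(diff* <= 0), P(diff* >= 0))`` floored at 1/n_boot, with a 95%
    percentile confidence interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs n >= 3")
    if paired and x.size != y.size:
        raise ValueError("paired samples must have equal length")
    rng = np.random.default_rng(seed)
    if paired:
        d = x - y
        idx = rng.integers(0, d.size, size=(n_boot, d.size))
        boot = d[idx].mean(axis=1)
    else:
        ix = rng.integers(0, x.size, size=(n_boot, x.size))
        iy = rng.integers(0, y.size, size=(n_boot, y.size))
        boot = x[ix].mean(axis=1) - y[iy].mean(axis=1)
    p = 2 * min((boot <= 0).mean(), (boot >= 0).mean())
    p = float(np.clip(p, 1.0 / n_boot, 1.0))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return BootstrapResult(
        estimate=float(x.mean() - y.mean()), ci=(float(lo), float(hi)),
        p_two_sided=p, n_boot=n_boot, seed=seed, paired=paired,
    )


def _clean(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    sub = table[cols].apply(pd.to_numeric, errors="coerce")
    kept = sub.dropna()
    dropped = len(sub) - len(kept)
    if dropped:
        logger.info("listwise deletion dropped %d of %d rows for %s",
                    dropped, len(sub), cols)
    return kept


def _ols_report(data: pd.DataFrame, response: str,
                predictors: list[str]) -> RegressionReport:
    y = data[response].to_numpy(dtype=float)
    X = sm.add_constant(data[predictors].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = data[predictors].corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if len(predictors) > 1 else (predictors[0],)
        raise ValueError(f"rank-deficient design; near-collinear columns: {worst}")
    res = sm.OLS(y, X).fit()
    names = ["const"] + predictors
    return RegressionReport(
        response=response, predictors=list(predictors),
        coefficients=dict(zip(names, res.params)),
        f_stat=float(res.fvalue), df=(int(res.df_model), int(res.df_resid)),
        r_squared=float(res.rsquared), p_overall=float(res.f_pvalue),
        p_per_coef=dict(zip(names, res.pvalues)), n=int(res.nobs),
    )


def univariate_screen(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] | None = None,
    fdr: bool = False,
) -> list[RegressionReport]:
    """One simple OLS fit (with intercept) per predictor.

    Constant predictors are skipped with a log entry.  With ``fdr=True``
    Benjamini-Hochberg-adjusted overall p-values are appended to each
    report's ``p_per_coef`` under ``"fdr"``.
    """
    if predictors is None:
        predictors = [c for c in COVARIATE_NAMES if c in table.columns]
    if response not in table.columns:
        raise ValueError(f"response column {response!r} missing")
    reports = []
    for pred in predictors:
        data = _clean(table, [response, pred])
        if data.shape[0] < 3:
            logger.warning("skipping %s: fewer than 3 complete rows", pred)
            continue
        if data[pred].nunique() <= 1:
            logger.warning("skipping constant predictor %s", pred)
            continue
        reports.append(_ols_report(data, response, [pred]))
    if fdr and reports:
        adj = multipletests([r.p_overall for r in reports], method="fdr_bh")[1]
        for r, q in zip(reports, adj):
            r.p_per_coef["fdr"] = float(q)
    return reports


def multivariate_fit(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] | None = None,
) -> RegressionReport:
    """Full OLS of the response on all predictors jointly."""
    if predictors is None:
        predictors = [c for c in COVARIATE_NAMES if c in table.columns]
    data = _clean(table, [response] + list(predictors))
    if data.shape[0] <= len(predictors) + 1:
        raise ValueError(
            f"n={data.shape[0]} leaves no residual degrees of freedom "
            f"for {len(predictors)} predictors")
    return _ols_report(data, response, list(predictors))


def cohort_summary(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-column n, mean, SD (n−1), min and max."""
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    for col in columns:
        vals = pd.to_numeric(table[col], errors="coerce").dropna()
        if vals.empty:
            raise ValueError(f"column {col!r} has no numeric values")
        rows.append({"column": col, "n": len(vals), "mean": vals.mean(),
                     "sd": vals.std(ddof=1), "min": vals.min(), "max": vals.max()})
    return pd.DataFrame(rows).set_index("column")


# Published cohort aggregates checked by the reproduction runner, with
# rounding tolerances (half a unit in the last printed digit).
REFERENCE_AGGREGATES: dict[str, dict[str, tuple[float, float]]] = {
    "axial": {
        "dsc_immediate_tde": (0.92, 0.005),
        "dsc_delayed_tde": (0.74, 0.005),
        "tau": (92.0, 0.5),
        "C": (284.0, 0.5),
        "t_shift": (0.7, 0.05),
        "r2_dsc_delayed_on_csf_above": (0.13, 0.005),
    },
    "sagittal": {
        "dsc_immediate_tde": (0.94, 0.005),
        "dsc_delayed_tde": (0.82, 0.005),
        "tau": (108.0, 0.5),
        "C": (120.0, 0.5),
        "t_shift": (2.6, 0.05),
    },
}

#: Default column roles; a column-mapping config handles header variants.
DEFAULT_COLUMN_MAP = {
    "dsc_immediate_tde": "dsc_immediate_tde",
    "dsc_delayed_tde": "dsc_delayed_tde",
    "tau": "tau",
    "C": "C",
    "t_shift": "t_shift",
    "csf_above": "csf_above",
}


def _load_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def reproduce_supplementary(
    s1_path: str | Path,
    s2_path: str | Path | None = None,
    column_map: dict[str, str] | None = None,
    reference: dict | None = None,
    tolerance_scale: float = 1.0,
) -> pd.DataFrame:
    """Recompute published cohort aggregates from per-patient tables.

    ``s1_path``/``s2_path`` are the axial and sagittal per-patient tables
    (CSV or spreadsheet).  For each plane the runner recomputes the mean
    DSC(Immediate, TDE) and DSC(Delayed, TDE), the mean τ, C and t_shift,
    and (axial only) the univariate R² of DSC(Delayed, TDE) on CSF_Above,
    then compares each against the published value within its rounding
    tolerance (scaled by ``tolerance_scale``; 0 gives exact-match mode).

    Returns a tidy pass/fail table with columns plane, check, computed,
    reference, tolerance, passed.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    reference = reference or REFERENCE_AGGREGATES
    rows = []
    for plane, path in (("axial", s1_path), ("sagittal", s2_path)):
        if path is None:
            continue
        table = _load_table(path)
        missing = [v for v in cmap.values()
                   if v not in table.columns and v != cmap["csf_above"]]
        if missing:
            raise ValueError(f"{plane} table is missing required columns: {missing}")
        checks = reference[plane]
        for check, (ref_val, tol) in checks.items():
            if check == "r2_dsc_delayed_on_csf_above":
                if cmap["csf_above"] not in table.columns:
                    raise ValueError(
                        f"{plane} table is missing required column "
                        f"{cmap['csf_above']!r}")
                rep = univariate_screen(
                    table.rename(columns={v: k for k, v in cmap.items()}),
                    response="dsc_delayed_tde", predictors=["csf_above"])[0]
                computed = rep.r_squared
            else:
                computed = float(pd.to_numeric(
                    table[cmap[check]], errors="coerce").dropna().mean())
            tol_eff = tol * tolerance_scale
            rows.append({
                "plane": plane, "check": check, "computed": computed,
                "reference": ref_val, "tolerance": tol_eff,
                "passed": bool(abs(computed - ref_val) <= tol_eff),
            })
    return pd.DataFrame(rows)


def format_reproduction_report(report: pd.DataFrame) -> str:
    """Plain-text pass/fail table for the reproduction runner."""
    lines = [f"{'plane':<9}{'check':<34}{'computed':>10}{'reference':>11}"
             f"{'tol':>8}  result"]
    for _, r in report.iterrows():
        lines.append(
            f"{r['plane']:<9}{r['check']:<34}{r['computed']:>10.4f}"
            f"{r['reference']:>11.4f}{r['tolerance']:>8.3f}  "
            + ("PASS" if r["passed"] else "FAIL"))
    n_fail = int((~report["passed"]).sum())
    lines.append(f"{len(report) - n_fail}/{len(report)} checks passed")
    return "\n".join(lines)
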