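"""Study orchestration: generate/load a cohort, measure, compare, model.

``run_study`` executes the full analysis a resolution-stratified diagnostic
study performs on paired zoomed/non-zoomed texture measurements:

1. descriptive statistics of every quantitative variable across the
   covariate strata, with rank-biserial effect sizes and Mann–Whitney p;
2. paired zoomed vs non-zoomed comparisons (Wilcoxon signed-rank) per
   resolution group and class;
3. multivariable logistic models for class membership — one per viewing
   condition and one combined — with ORs, Wald CIs and an LR test;
4. ROC/Youden analysis of each metric, stratified by resolution group and
   viewing condition.

Every cell of every table is produced by one call into :mod:`panotex.stats`;
strata too small to estimate (a class below 3) are reported as
not-estimable rather than dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as px_stats
from .phantom import CohortSpec, cohort_from_csv, cohort_to_dataframe, sample_cohort

log = logging.getLogger("panotex.pipeline")

METRIC_COLUMNS = [
    "xpar_non_zoomed",
    "power_xpar_non_zoomed",
    "pixel_count_non_zoomed",
    "xpar_zoomed",
    "power_xpar_zoomed",
    "pixel_count_zoomed",
]

_METRICS = ["xpar", "power_xpar", "pixel_count"]
_CONDITIONS = ["zoomed", "non_zoomed"]

#: minimum per-class size for an estimable ROC stratum
MIN_CLASS_N = 3


@dataclass
class StudyConfig:
    """Configuration of one study run.

    Exactly one cohort source: a :class:`CohortSpec` to generate from, or
    a path to an existing cohort CSV.
    """

    cohort: CohortSpec | None = None
    cohort_csv: str | None = None
    alpha: float = 0.05
    seed: int = 0
    output_dir: str = "study_out"

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.cohort_csv is None):
            raise ValueError("specify exactly one of cohort spec or cohort CSV")

    def fingerprint(self) -> str:
        if self.cohort is not None:
            payload = json.dumps(dataclasses.asdict(self.cohort),
                                 default=str, sort_keys=True)
        else:
            payload = str(self.cohort_csv)
        payload += f"|alpha={self.alpha}|seed={self.seed}"
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    descriptives: pd.DataFrame
    zoom_comparison: pd.DataFrame
    logistic: pd.DataFrame
    roc: pd.DataFrame
    config_fingerprint: str
    seed: int

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "descriptives": self.descriptives,
            "zoom_comparison": self.zoom_comparison,
            "logistic": self.logistic,
            "roc": self.roc,
        }

    def summary_dict(self) -> dict:
        return {
            "config_fingerprint": self.config_fingerprint,
            "seed": self.seed,
            "tables": {k: v.to_dict(orient="records") for k, v in self.tables().items()},
        }


def _descriptive_row(values: np.ndarray, alpha: float) -> dict:
    n = values.size
    mean = float(values.mean()) if n else np.nan
    sd = float(values.std(ddof=1)) if n > 1 else np.nan
    half = sps.t.ppf(1 - alpha / 2, n - 1) * sd / np.sqrt(n) if n > 1 else np.nan
    return {
        "n": n,
        "minimum": float(values.min()) if n else np.nan,
        "maximum": float(values.max()) if n else np.nan,
        "mean": mean,
        "median": float(np.median(values)) if n else np.nan,
        "sd": sd,
        "ci_low": mean - half if n > 1 else np.nan,
        "ci_high": mean + half if n > 1 else np.nan,
    }


_STRATIFIERS = {
    "sex": ("female", "male"),
    "age_group": ("17-39", "40-54"),
    "c_shaped": (False, True),
    "resolution_group": ("group_496", "group_593"),
}

_DESCRIBED = ["dentin_pulp_volume", "pulp_length"] + METRIC_COLUMNS


def descriptives_table(df: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable, per-stratum descriptives with two-group rank comparison."""
    rows = []
    for var in _DESCRIBED:
        for strat, levels in _STRATIFIERS.items():
            groups = [df.loc[df[strat] == lev, var].to_numpy(float) for lev in levels]
            test = None
            if all(g.size > 0 for g in groups):
                test = px_stats.mann_whitney(groups[0], groups[1])
            for lev, g in zip(levels, groups):
                row = {"variable": var, "stratifier": strat, "group": str(lev)}
                row.update(_descriptive_row(g, alpha))
                row["effect_r"] = test.effect_r if test else np.nan
                row["p_value"] = test.p_value if test else np.nan
                rows.append(row)
    return pd.DataFrame(rows)


def zoom_comparison_table(df: pd.DataFrame) -> pd.DataFrame:
    """Paired zoomed vs non-zoomed Wilcoxon tests per resolution x class."""
    rows = []
    for res in sorted(df["resolution_group"].unique()):
        for c_shaped in (False, True):
            sub = df[(df["resolution_group"] == res) & (df["c_shaped"] == c_shaped)]
            for metric in _METRICS:
                z_col, n_col = f"{metric}_zoomed", f"{metric}_non_zoomed"
                row = {
                    "resolution_group": res,
                    "c_shaped": c_shaped,
                    "metric": metric,
                    "n": len(sub),
                }
                if len(sub) >= 2:
                    t = px_stats.wilcoxon_signed_rank(sub[z_col], sub[n_col])
                    row.update(
                        zoomed_mean=float(sub[z_col].mean()),
                        non_zoomed_mean=float(sub[n_col].mean()),
                        z_statistic=t.statistic,
                        p_value=t.p_value,
                        degenerate=t.degenerate,
                    )
                else:
                    row.update(zoomed_mean=np.nan, non_zoomed_mean=np.nan,
                               z_statistic=np.nan, p_value=np.nan, degenerate=True)
                rows.append(row)
    return pd.DataFrame(rows)


def _logistic_rows(df: pd.DataFrame, model_name: str, cols: list[str],
                   extra: list[str]) -> list[dict]:
    names = cols + extra
    design = np.column_stack(
        [df[c].to_numpy(float) for c in cols]
        + [_encode(df, c) for c in extra]
    )
    y = df["c_shaped"].to_numpy(bool)
    res = px_stats.logistic_model(design, y, predictor_names=names)
    rows = []
    for p in res.predictors:
        rows.append(
            {
                "model": model_name,
                "predictor": p.name,
                "odds_ratio": p.odds_ratio,
                "ci_low": p.ci_low,
                "ci_high": p.ci_high,
                "p_value": p.p_value,
                "lr_chi2": res.lr_chi2,
                "lr_df": res.df,
                "lr_p": res.lr_p,
                "model_auc": res.in_sample_auc,
                "separation_flag": res.separation_flag,
            }
        )
    return rows


def _encode(df: pd.DataFrame, col: str) -> np.ndarray:
    """Binary-encode the categorical covariates used in the models."""
    if col == "resolution_group":
        return (df[col] == "group_593").to_numpy(float)  # 0 = 496, 1 = 593
    if col == "sex":
        return (df[col] == "male").to_numpy(float)
    if col == "age_group":
        return (df[col] == "40-54").to_numpy(float)
    return df[col].to_numpy(float)


def logistic_table(df: pd.DataFrame) -> pd.DataFrame:
    """Models A1 (zoomed), A2 (non-zoomed) and A3 (combined)."""
    extra = ["resolution_group", "sex", "age_group"]
    zoomed = [f"{m}_zoomed" for m in _METRICS]
    nonz = [f"{m}_non_zoomed" for m in _METRICS]
    rows = []
    rows += _logistic_rows(df, "A1_zoomed", zoomed, extra)
    rows += _logistic_rows(df, "A2_non_zoomed", nonz, extra)
    rows += _logistic_rows(df, "A3_combined", zoomed + nonz, extra)
    return pd.DataFrame(rows)


def roc_table(df: pd.DataFrame) -> pd.DataFrame:
    """ROC/Youden per resolution group x condition x metric.

    Strata in which either class has fewer than ``MIN_CLASS_N`` teeth are
    reported with ``estimable = False`` (the unbalanced split makes this
    path reachable) rather than silently dropped.
    """
    rows = []
    for res in sorted(df["resolution_group"].unique()):
        sub = df[df["resolution_group"] == res]
        y = sub["c_shaped"].to_numpy(bool)
        for cond in _CONDITIONS:
            for metric in _METRICS:
                col = f"{metric}_{cond}"
                row = {
                    "resolution_group": res,
                    "condition": cond,
                    "metric": metric,
                    "n_pos": int(y.sum()),
                    "n_neg": int((~y).sum()),
                }
                if y.sum() >= MIN_CLASS_N and (~y).sum() >= MIN_CLASS_N:
                    r = px_stats.roc_with_youden(sub[col].to_numpy(float), y)
                    row.update(
                        estimable=True,
                        auc=r.auc,
                        threshold_rule=r.threshold_rule,
                        threshold=r.threshold,
                        direction=r.direction.value,
                        sensitivity=r.sensitivity,
                        specificity=r.specificity,
                        youden_j=r.youden_j,
                    )
                else:
                    row.update(estimable=False, auc=np.nan, threshold_rule="",
                               threshold=np.nan, direction="", sensitivity=np.nan,
                               specificity=np.nan, youden_j=np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full study; deterministic given config (incl. seed)."""
    if config.cohort is not None:
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        log.info("stage=generate n=%d", spec.n_c_shaped + spec.n_control)
        df = cohort_to_dataframe(sample_cohort(spec))
    else:
        log.info("stage=load csv=%s", config.cohort_csv)
        df = cohort_from_csv(config.cohort_csv)
    log.info("stage=measure records=%d", len(df))

    if len(df) == 0:
        empty = pd.DataFrame()
        return StudyReport(empty, empty, empty, empty,
                           config.fingerprint(), config.seed)

    desc = descriptives_table(df, alpha=config.alpha)
    log.info("stage=describe rows=%d", len(desc))
    zoom = zoom_comparison_table(df)
    log.info("stage=zoom_compare rows=%d", len(zoom))
    logit = logistic_table(df)
    log.info("stage=model rows=%d", len(logit))
    roc = roc_table(df)
    log.info("stage=roc rows=%d", len(roc))
    return StudyReport(desc, zoom, logit, roc, config.fingerprint(), config.seed)


def export_report(report: StudyReport, out_dir: str | Path,
                  config: StudyConfig | None = None) -> list[str]:
    """Write one CSV per table plus a JSON summary; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    for name, table in report.tables().items():
        path = out / f"{name}.csv"
        table.to_csv(path, index=False)
        manifest.append(path.name)
    summary = out / "summary.json"
    summary.write_text(json.dumps(report.summary_dict(), indent=2, default=str))
    manifest.append(summary.name)
    if config is not None:
        cfg_path = out / "config.json"
        payload = {
            "alpha": config.alpha,
            "seed": config.seed,
            "fingerprint": config.fingerprint(),
            "cohort": dataclasses.asdict(config.cohort) if config.cohort else None,
            "cohort_csv": config.cohort_csv,
        }
        cfg_path.write_text(json.dumps(payload, indent=2, default=str))
        manifest.append(cfg_path.name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
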