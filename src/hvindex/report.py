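"""Full-study orchestration: one cohort table in, report tables out.

``run_study`` reproduces the complete analysis battery for a graft cohort:

* pooled Spearman correlations of angle, area and HV index against the
  pressure gradient (the "which predictor tracks hemodynamics best" table);
* the same correlations within each timepoint, feeding a Fisher-z test of
  equality of the per-timepoint coefficients for each predictor;
* Kruskal-Wallis across timepoints plus Steel-Dwass all-pairs posthoc for
  gradient, HV index, area and angle;
* MINE statistics for the three pooled predictor/gradient pairs;
* per-timepoint summary statistics (mean, SEM, median, range);
* optional densitometry (Kruskal-Wallis + Steel-Dwass per protein) and
  two-group assay (Wilcoxon rank-sum per analyte) comparisons.

Records without a complete pressure pair are excluded from gradient-based
analyses and listed in the report's skip log; undersized groups are skipped
the same way, never silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import correlation_heterogeneity, spearman
from .group_tests import (kruskal_wallis, significance_stars, steel_dwass,
                          wilcoxon_rank_sum)
from .measurements import CohortTable
from .mine import MineParams, mine_stats

logger = logging.getLogger(__name__)

__all__ = ["StudyReport", "run_study", "summarize_groups", "write_report"]

#: predictor column -> row label used in the report tables
PREDICTORS = {
    "angle_deg": "angle",
    "area_mm2": "area",
    "hv_index": "hv_index",
}
QUANTITIES = ("gradient_mmhg", "hv_index", "area_mm2", "angle_deg")

MIN_GROUP_N = 4  # smallest per-timepoint n for a correlation


@dataclass
class StudyReport:
    """All output tables of one study run."""

    table1: pd.DataFrame          # pooled correlations per predictor
    per_month_rho: pd.DataFrame   # per-timepoint correlations
    heterogeneity: pd.DataFrame   # equality-of-correlations test per predictor
    group_stats: pd.DataFrame     # per-timepoint summaries per quantity
    posthoc: pd.DataFrame         # Steel-Dwass pairs per quantity
    kruskal: pd.DataFrame         # Kruskal-Wallis per quantity
    table2: pd.DataFrame          # MINE statistics per predictor
    densitometry: pd.DataFrame | None = None
    assays: pd.DataFrame | None = None
    skipped: list = field(default_factory=list)


def summarize_groups(cohort: CohortTable, quantity: str) -> pd.DataFrame:
    """Per-timepoint n, mean, SEM, median, min, max for one quantity.

    SEM is sd / sqrt(n) with the n-1 denominator sd; a single-observation
    group reports SEM as missing.
    """
    rows = []
    for tp in cohort.timepoints():
        vals = cohort.values(quantity, timepoint=tp)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        sem = (float(np.std(vals, ddof=1)) / np.sqrt(len(vals))
               if len(vals) > 1 else np.nan)
        rows.append({
            "quantity": quantity, "timepoint": tp, "n": len(vals),
            "mean": float(np.mean(vals)), "sem": sem,
            "median": float(np.median(vals)),
            "min": float(np.min(vals)), "max": float(np.max(vals)),
        })
    if not rows:
        raise ValueError(f"no finite values for {quantity!r}")
    return pd.DataFrame(rows)


def _correlations(cohort: CohortTable, spearman_method: str,
                  skipped: list) -> tuple[pd.DataFrame, pd.DataFrame,
                                          pd.DataFrame]:
    df = cohort.df
    complete = df[np.isfinite(df["gradient_mmhg"])]
    n_dropped = len(df) - len(complete)
    if n_dropped:
        skipped.append(f"{n_dropped} record(s) without a pressure pair "
                       "excluded from correlation analyses")

    pooled_rows, per_month_rows, het_rows = [], [], []
    for col, label in PREDICTORS.items():
        res = spearman(complete[col], complete["gradient_mmhg"],
                       method="approx" if len(complete) > 10 else spearman_method,
                       label=f"{label}|pooled")
        pooled_rows.append({
            "predictor": label, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "rho": res.rho, "p": res.p, "n": res.n,
        })

        rhos, ns = [], []
        for tp in cohort.timepoints():
            sub = complete[complete["timepoint"] == tp]
            if len(sub) < MIN_GROUP_N:
                skipped.append(
                    f"timepoint {tp}: n={len(sub)} < {MIN_GROUP_N}, "
                    f"no {label} correlation")
                continue
            r = spearman(sub[col], sub["gradient_mmhg"],
                         method=spearman_method, label=f"{label}|{tp}")
            per_month_rows.append({
                "predictor": label, "timepoint": tp, "rho": r.rho,
                "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p, "n": r.n,
            })
            if abs(r.rho) < 1.0:
                rhos.append(r.rho)
                ns.append(r.n)
            else:
                skipped.append(
                    f"timepoint {tp}: |rho| = 1 for {label}, excluded from "
                    "the heterogeneity test")
        if len(rhos) >= 2:
            het = correlation_heterogeneity(rhos, ns)
            het_rows.append({
                "predictor": label, "chi2": het.chi2, "df": het.df,
                "p": het.p, "pooled_z": het.pooled_z,
                "pooled_rho": het.pooled_rho, "k": len(rhos),
            })
        else:
            skipped.append(f"{label}: fewer than 2 usable per-timepoint "
                           "correlations, heterogeneity test skipped")
    return (pd.DataFrame(pooled_rows), pd.DataFrame(per_month_rows),
            pd.DataFrame(het_rows))


def _group_comparisons(cohort: CohortTable, posthoc_method: str,
                       n_resamples: int, seed: int,
                       skipped: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    kw_rows, posthoc_rows = [], []
    for quantity in QUANTITIES:
        groups, labels = [], []
        for tp in cohort.timepoints():
            vals = cohort.values(quantity, timepoint=tp)
            vals = vals[np.isfinite(vals)]
            if len(vals) < 2:
                skipped.append(f"{quantity} @ {tp}: n={len(vals)} < 2, "
                               "left out of group comparisons")
                continue
            groups.append(vals)
            labels.append(tp)
        if len(groups) < 2:
            skipped.append(f"{quantity}: fewer than 2 usable groups")
            continue
        kw = kruskal_wallis(groups)
        kw_rows.append({"quantity": quantity, "H": kw.H, "df": kw.df,
                        "p": kw.p, "stars": significance_stars(kw.p)})
        for pair in steel_dwass(groups, labels=labels, method=posthoc_method,
                                n_resamples=n_resamples, seed=seed):
            posthoc_rows.append({
                "quantity": quantity, "group_a": pair.group_a,
                "group_b": pair.group_b, "t_stat": pair.t_stat, "p": pair.p,
                "stars": significance_stars(pair.p), "method": pair.method,
            })
    return pd.DataFrame(kw_rows), pd.DataFrame(posthoc_rows)


def _mine_table(cohort: CohortTable, mine_params: MineParams,
                skipped: list) -> pd.DataFrame:
    df = cohort.df
    complete = df[np.isfinite(df["gradient_mmhg"])]
    rows = []
    for col, label in PREDICTORS.items():
        res = mine_stats(complete[col], complete["gradient_mmhg"],
                         params=mine_params)
        rows.append({"predictor": label, "MIC": res.mic, "MAS": res.mas,
                     "MCN": res.mcn, "MIC_R2": res.mic_r2, "TIC": res.tic})
    return pd.DataFrame(rows)


def _densitometry_tests(table: pd.DataFrame, posthoc_method: str,
                        n_resamples: int, seed: int) -> pd.DataFrame:
    rows = []
    for protein, sub in table.groupby("protein", sort=False):
        groups, labels = [], []
        for tp, g in sub.groupby("timepoint", sort=False):
            groups.append(g["ratio"].to_numpy(dtype=float))
            labels.append(str(tp))
        kw = kruskal_wallis(groups)
        rows.append({"protein": protein, "comparison": "all",
                     "statistic": kw.H, "p": kw.p,
                     "stars": significance_stars(kw.p), "test": "kruskal"})
        for pair in steel_dwass(groups, labels=labels, method=posthoc_method,
                                n_resamples=n_resamples, seed=seed):
            rows.append({"protein": protein,
                         "comparison": f"{pair.group_a} vs {pair.group_b}",
                         "statistic": pair.t_stat, "p": pair.p,
                         "stars": significance_stars(pair.p),
                         "test": "steel_dwass"})
    return pd.DataFrame(rows)


def _assay_tests(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for analyte, sub in table.groupby("analyte", sort=False):
        groups = list(sub.groupby("group", sort=False))
        if len(groups) != 2:
            raise ValueError(
                f"assay {analyte!r} needs exactly 2 groups, got {len(groups)}")
        (name_a, ga), (name_b, gb) = groups
        w, p = wilcoxon_rank_sum(ga["concentration"].to_numpy(dtype=float),
                                 gb["concentration"].to_numpy(dtype=float))
        rows.append({"analyte": analyte,
                     "comparison": f"{name_a} vs {name_b}", "W": w, "p": p,
                     "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def run_study(cohort: CohortTable,
              densitometry: pd.DataFrame | None = None,
              assays: pd.DataFrame | None = None,
              seed: int = 0,
              spearman_method: str = "auto",
              posthoc_method: str = "asymptotic",
              n_resamples: int = 100_000,
              mine_params: MineParams | None = None) -> StudyReport:
    """Run the complete analysis battery on one cohort.

    Deterministic given the cohort and ``seed`` (the seed only matters for
    permutation-mode posthoc tests).
    """
    if len(cohort.timepoints()) < 2:
        raise ValueError("need at least 2 timepoints")
    skipped: list[str] = []

    logger.info("study: %d records, %d timepoints", cohort.n_records,
                len(cohort.timepoints()))
    table1, per_month, het = _correlations(cohort, spearman_method, skipped)
    logger.info("correlations: %d pooled, %d per-timepoint",
                len(table1), len(per_month))
    kw, posthoc = _group_comparisons(cohort, posthoc_method, n_resamples,
                                     seed, skipped)
    logger.info("group tests: %d Kruskal-Wallis, %d posthoc pairs",
                len(kw), len(posthoc))
    table2 = _mine_table(cohort, mine_params or MineParams(), skipped)

    group_stats = pd.concat(
        [summarize_groups(cohort, q) for q in QUANTITIES], ignore_index=True)

    dens = (None if densitometry is None
            else _densitometry_tests(densitometry, posthoc_method,
                                     n_resamples, seed))
    assay = None if assays is None else _assay_tests(assays)
    for msg in skipped:
        logger.warning("skipped: %s", msg)

    return StudyReport(table1=table1, per_month_rho=per_month,
                       heterogeneity=het, group_stats=group_stats,
                       posthoc=posthoc, kruskal=kw, table2=table2,
                       densitometry=dens, assays=assay, skipped=skipped)


_FLOAT_FORMAT = "%.6g"


def write_report(report: StudyReport, outdir: str | Path,
                 plots: bool = False, cohort: CohortTable | None = None
                 ) -> list[Path]:
    """Write every report table as CSV into ``outdir``; returns the paths.

    With ``plots=True`` (and the cohort supplied) box-and-whisker panels of
    gradient and HV index by timepoint are saved alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "table1.csv": report.table1,
        "per_month_rho.csv": report.per_month_rho,
        "heterogeneity.csv": report.heterogeneity,
        "group_stats.csv": report.group_stats,
        "posthoc.csv": report.posthoc,
        "kruskal.csv": report.kruskal,
        "table2.csv": report.table2,
    }
    if report.densitometry is not None:
        tables["densitometry_tests.csv"] = report.densitometry
    if report.assays is not None:
        tables["assay_tests.csv"] = report.assays
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
        written.append(path)
    if report.skipped:
        path = outdir / "skipped.txt"
        path.write_text("\n".join(report.skipped) + "\n")
        written.append(path)

    if plots and cohort is not None:
        written.extend(_boxplots(cohort, outdir))
    return written


def _boxplots(cohort: CohortTable, outdir: Path) -> list[Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    for quantity, ylabel in (("gradient_mmhg", "pressure gradient (mmHg)"),
                             ("hv_index", "HV index (deg/mm$^2$)")):
        tps = cohort.timepoints()
        data = [cohort.values(quantity, timepoint=tp) for tp in tps]
        data = [d[np.isfinite(d)] for d in data]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.boxplot(data, tick_labels=tps, showmeans=True)
        ax.set_xlabel("timepoint (months)")
        ax.set_ylabel(ylabel)
        fig.tight_layout()
        path = outdir / f"box_{quantity}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths
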