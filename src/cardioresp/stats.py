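"""Nonparametric group comparisons and tidy study-level reporting.

Small-cohort physiology studies compare groups with the Mann–Whitney U
test and within-subject changes with the Wilcoxon signed-rank test,
both two-sided; effect sizes are reported as Cohen's d.  Exact null
distributions are used at small sample sizes without ties, the normal
approximation (tie-corrected) otherwise.  Mixed-effects modelling is
intentionally left to external tools; the report emits tidy per-animal
rows ready for such fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "mann_whitney_u", "wilcoxon_signed_rank",
           "cohens_d", "study_report"]

EXACT_MW_MAX_N = 8  # exact U distribution up to this min(n_x, n_y)
EXACT_WILCOXON_MAX_N = 12


@dataclass
class GroupComparison:
    """Result of one two-sided nonparametric comparison."""

    statistic_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    effect_size_d: Optional[float] = None
    method: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _has_ties(*samples: np.ndarray) -> bool:
    pooled = np.concatenate(samples)
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y) -> GroupComparison:
    """Two-sided Mann–Whitney U test.

    Exact when ``min(n_x, n_y) <= 8`` and there are no ties; otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    exact = min(x.size, y.size) <= EXACT_MW_MAX_N and not _has_ties(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return GroupComparison(
        statistic_name="U", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=(x.size, y.size),
        method="exact" if exact else "normal-approx",
    )


def wilcoxon_signed_rank(before, after) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Exact for ``n <= 12`` nonzero differences without tied absolute
    differences; normal approximation otherwise.  Zero differences are
    dropped (Wilcoxon's convention); all-zero differences are an error.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size or before.size == 0:
        raise ValueError("paired samples of equal, nonzero length required")
    d = after - before
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    exact = (nz.size <= EXACT_WILCOXON_MAX_N
             and np.unique(np.abs(nz)).size == nz.size)
    res = sps.wilcoxon(before, after,
                       zero_method="wilcox", correction=False,
                       alternative="two-sided",
                       method="exact" if exact else "asymptotic")
    return GroupComparison(
        statistic_name="W", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=(nz.size,),
        method="exact" if exact else "normal-approx",
    )


def cohens_d(mean_diff: float, sd_pooled: float) -> float:
    """Cohen's d: mean difference over the pooled standard deviation."""
    if not sd_pooled > 0:
        raise ValueError("pooled SD must be positive")
    return mean_diff / sd_pooled


def _sem(x: pd.Series) -> float:
    return 0.0 if len(x) < 2 else float(x.std(ddof=1) / np.sqrt(len(x)))


def _section(per_animal: pd.DataFrame,
             value_cols: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group mean ± SEM per value column, plus between-group tests."""
    keys = [c for c in ("group", "phase", "stage", "condition")
            if c in per_animal.columns]
    grouped = per_animal.groupby(keys) if keys else None
    rows = []
    if grouped is not None:
        for name, sub in grouped:
            name = name if isinstance(name, tuple) else (name,)
            row = dict(zip(keys, name))
            row["n"] = len(sub)
            for c in value_cols:
                row[f"{c}_mean"] = float(sub[c].mean())
                row[f"{c}_sem"] = _sem(sub[c])
            rows.append(row)
    summary = pd.DataFrame(rows)

    tests = []
    if "group" in per_animal.columns:
        groups = sorted(per_animal["group"].unique())
        strata_keys = [k for k in keys if k != "group"]
        strata = (per_animal.groupby(strata_keys)
                  if strata_keys else [((), per_animal)])
        if len(groups) == 2:
            for sname, sub in strata:
                sname = sname if isinstance(sname, tuple) else (sname,)
                for c in value_cols:
                    a = sub.loc[sub["group"] == groups[0], c].dropna()
                    b = sub.loc[sub["group"] == groups[1], c].dropna()
                    if len(a) == 0 or len(b) == 0:
                        continue
                    cmp = mann_whitney_u(a, b)
                    tests.append({
                        **dict(zip(strata_keys, sname)), "variable": c,
                        "test": "mann-whitney-u", "U": cmp.statistic,
                        "p_value": cmp.p_value,
                        "n": f"{len(a)}/{len(b)}",
                    })
    return summary, pd.DataFrame(tests)


def study_report(bp: pd.DataFrame | None = None,
                 hrv: pd.DataFrame | None = None,
                 hvr: pd.DataFrame | None = None,
                 sleep_ventilation: pd.DataFrame | None = None,
                 sleep_events: pd.DataFrame | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Assemble tidy per-section tables with group mean ± SEM and
    nonparametric between-group p-values.

    Each input is a per-animal data frame with a ``group`` column and
    the section's value columns (e.g. BP: ``phase, map, sbp, dbp, hr``).
    Missing sections are reported as explicit gaps.  When ``out_dir``
    is given, each section is written as CSV and an overview as JSON.
    """
    sections = {
        "bp": (bp, ["map", "sbp", "dbp", "hr"]),
        "hrv": (hrv, ["lf_ms2", "hf_ms2", "lf_hf"]),
        "hvr": (hvr, ["ve_normoxia", "ve_hypoxia", "hvr"]),
        "sleep_ventilation": (sleep_ventilation,
                              ["v_t_ml", "rr_bpm", "ve_norm"]),
        "sleep_events": (sleep_events,
                         ["apnea_index", "odi"]),
    }
    report: dict = {"sections": {}, "gaps": []}
    for name, (table, cols) in sections.items():
        if table is None or len(table) == 0:
            report["gaps"].append(name)
            continue
        use = [c for c in cols if c in table.columns]
        summary, tests = _section(table, use)
        report["sections"][name] = {
            "per_animal": table, "summary": summary, "tests": tests,
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        overview = {"gaps": report["gaps"], "sections": {}}
        for name, sec in report["sections"].items():
            sec["per_animal"].to_csv(out / f"{name}_per_animal.csv",
                                     index=False)
            sec["summary"].to_csv(out / f"{name}_summary.csv", index=False)
            if len(sec["tests"]):
                sec["tests"].to_csv(out / f"{name}_tests.csv", index=False)
            overview["sections"][name] = {
                "n_rows": int(len(sec["per_animal"])),
                "n_tests": int(len(sec["tests"])),
            }
        (out / "report.json").write_text(json.dumps(overview, indent=1))
    return report
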