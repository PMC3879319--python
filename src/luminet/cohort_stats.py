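"""Clinical cohort statistics: H-scores, association screens, survival.

Immunohistochemical staining is summarised by the H-score
``sum(intensity x percent cells)`` over intensity levels 0-3, giving a
0-300 scale; tumours are grouped as negative (score 0), low (0 < score
< 200) or high (score >= 200, strong positivity), with binary
present/absent derived as score > 0.

Association screens use the uncorrected Pearson chi-square (no Yates
continuity correction — the convention the packaged reference tables were
computed under). Survival uses the Kaplan-Meier product-limit estimator
with the Mantel-Cox log-rank test and Cox proportional-hazards regression
(Efron tie handling), all via lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2_contingency

from luminet.exceptions import DataError, StatsError

__all__ = [
    "compute_hscore",
    "categorize_expression",
    "chi_square_test",
    "kaplan_meier",
    "log_rank_test",
    "cox_ph",
    "association_screen",
    "ScreenResult",
]


def compute_hscore(records: list[tuple[int, float]]) -> float:
    """H-score from (staining intensity, percent of cells) records.

    Intensities are integers 0-3, each appearing at most once; percentages
    must not exceed 100 in total. Returns ``sum(intensity * percent)``,
    a value in [0, 300].
    """
    intensities = [r[0] for r in records]
    percents = [r[1] for r in records]
    if any(int(i) != i or not 0 <= i <= 3 for i in intensities):
        raise DataError("staining intensities must be integers in 0..3")
    if len(set(intensities)) != len(intensities):
        raise DataError("each staining intensity may appear only once")
    if any(p < 0 or p > 100 for p in percents):
        raise DataError("percent of cells must be in [0, 100]")
    if sum(percents) > 100 + 1e-9:
        raise DataError(
            f"percentages sum to {sum(percents)}, which exceeds 100"
        )
    return float(sum(i * p for i, p in records))


def categorize_expression(score: float) -> str:
    """Group an H-score as ``negative`` (0), ``high`` (>=200) or ``low``."""
    if not 0 <= score <= 300:
        raise DataError(f"H-score {score} outside the valid range [0, 300]")
    if score == 0:
        return "negative"
    if score >= 200:
        return "high"
    return "low"


def _as_counts(table) -> np.ndarray:
    counts = (
        table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table)
    )
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise StatsError("contingency table must be at least 2x2")
    if (counts < 0).any():
        raise StatsError("contingency counts must be nonnegative")
    return counts


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, without continuity correction.

    Returns ``(statistic, df, p)`` with ``df = (r-1)(c-1)`` and expected
    counts from the product of margins over the table total.
    """
    counts = _as_counts(table)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise StatsError("contingency table has a zero margin")
    stat, p, df, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def _check_survival(records: pd.DataFrame, time_col: str, event_col: str) -> None:
    if (records[time_col] <= 0).any():
        raise DataError("survival times must be positive")
    if not records[event_col].isin((0, 1)).all():
        raise DataError("event indicators must be 0/1")


def kaplan_meier(
    records: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    group_col: str | None = "group",
) -> dict[str, pd.Series]:
    """Product-limit survival estimates, one stepwise curve per group.

    Right-censoring (event 0) is respected. Returns, per group, the
    estimated survival probability indexed by time (including t=0).
    """
    _check_survival(records, time_col, event_col)
    if group_col is None:
        groups = {"all": records}
    else:
        groups = {str(g): sub for g, sub in records.groupby(group_col)}
    curves = {}
    for name, sub in groups.items():
        if len(sub) == 0:
            raise StatsError(f"group {name!r} has no records")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], sub[event_col])
        curves[name] = kmf.survival_function_.iloc[:, 0].rename(name)
    return curves


def log_rank_test(
    records: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    group_col: str = "group",
) -> tuple[float, int, float]:
    """Mantel-Cox log-rank test across groups: (chi-square, df, p)."""
    _check_survival(records, time_col, event_col)
    n_groups = records[group_col].nunique()
    if n_groups < 2:
        raise StatsError("log-rank test requires at least two groups")
    if records[event_col].sum() < 1:
        raise StatsError("log-rank test requires at least one event")
    res = multivariate_logrank_test(
        records[time_col], records[group_col], records[event_col]
    )
    return float(res.test_statistic), int(n_groups - 1), float(res.p_value)


def cox_ph(
    records: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards regression (Efron tie handling).

    Returns one row per covariate with the hazard ratio exp(beta), its 95%
    confidence interval ``exp(beta +- 1.96 SE)`` and the Wald p-value. An
    empty covariate list returns an empty frame (null model).
    """
    cols = ["hazard_ratio", "ci_lower", "ci_upper", "p"]
    if not covariates:
        return pd.DataFrame(columns=cols)
    _check_survival(records, time_col, event_col)
    if records[event_col].sum() < 2:
        raise StatsError("Cox regression requires at least 2 events")
    data = records[[time_col, event_col, *covariates]].copy()
    cph = CoxPHFitter()
    cph.fit(data, duration_col=time_col, event_col=event_col)
    summary = cph.summary
    out = pd.DataFrame(
        {
            "hazard_ratio": summary["exp(coef)"],
            "ci_lower": np.exp(summary["coef"] - 1.96 * summary["se(coef)"]),
            "ci_upper": np.exp(summary["coef"] + 1.96 * summary["se(coef)"]),
            "p": summary["p"],
        }
    )
    out.index.name = "covariate"
    return out.loc[covariates, cols]


@dataclass
class ScreenResult:
    """One marker's association with the exposure."""

    marker: str
    table: pd.DataFrame | None
    statistic: float | None
    df: int | None
    p: float | None
    note: str = ""


def association_screen(
    cohort: pd.DataFrame, exposure: str, markers: list[str]
) -> list[ScreenResult]:
    """Chi-square association of each binary marker with a binary exposure.

    Builds, per marker, a 2x2 table of (marker absent/present) x (exposure
    absent/present) counts and tests it. A constant marker (or one whose
    table has a zero margin) yields a result with a note instead of a
    statistic; the screen continues.
    """
    if exposure not in cohort.columns:
        raise DataError(f"exposure column {exposure!r} not in cohort")
    missing = [m for m in markers if m not in cohort.columns]
    if missing:
        raise DataError(f"markers not in cohort: {missing}")
    exp = cohort[exposure].astype(int)
    results = []
    for marker in markers:
        mk = cohort[marker].astype(int)
        counts = pd.crosstab(mk, exp).reindex(
            index=[0, 1], columns=[0, 1], fill_value=0
        )
        table = pd.DataFrame(
            counts.to_numpy(),
            index=["Absent", "Present"],
            columns=[f"{exposure} absent", f"{exposure} present"],
        )
        try:
            stat, df, p = chi_square_test(table)
        except StatsError as exc:
            results.append(
                ScreenResult(marker, table, None, None, None, note=str(exc))
            )
            continue
        results.append(ScreenResult(marker, table, stat, df, p))
    return results


def screen_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    """Tabular association report: counts, percentages, chi-square, p."""
    rows = []
    for r in results:
        if r.table is not None:
            col_tot = r.table.sum(axis=0).to_numpy()
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = 100 * r.table.to_numpy() / np.where(col_tot == 0, 1, col_tot)
        for i, level in enumerate(r.table.index if r.table is not None else []):
            rows.append(
                {
                    "marker": r.marker,
                    "level": level,
                    "n_exposure_absent": int(r.table.iloc[i, 0]),
                    "pct_exposure_absent": round(float(pct[i, 0]), 2),
                    "n_exposure_present": int(r.table.iloc[i, 1]),
                    "pct_exposure_present": round(float(pct[i, 1]), 2),
                    "chi_square": r.statistic,
                    "df": r.df,
                    "p": r.p,
                    "note": r.note,
                }
            )
    return pd.DataFrame(rows)
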