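"""Week-1 → week-4 remodelling prediction statistics.

After infarction the left ventricle dilates and hypertrophies over weeks
(adverse remodelling). This module asks which week-1 MRI measurement best
predicts the week-4 outcome in a cohort of infarcted animals:

* a univariate Pearson correlation table of every week-1 predictor against
  every week-4 outcome, with two-sided p-values from the t-transform
  t = r·√(n−2)/√(1−r²);
* simple OLS regression of one outcome on one predictor (the headline
  relation is LV-EDV_wk4 on LV-ESV_wk1);
* stepwise forward selection with a partial-F entry test (p < 0.05 by
  default, no removal step) to find the smallest predictive model.

Sham-operated animals are carried in the table for reference but excluded
from all fitting by default — remodelling is a property of the infarcted
group.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortSchemaError, UndefinedCorrelationError

__all__ = [
    "PREDICTORS_WK1",
    "OUTCOMES_WK4",
    "CorrelationTable",
    "RegressionFit",
    "StepwiseStep",
    "StepwiseResult",
    "validate_cohort",
    "correlation_table",
    "ols_fit",
    "stepwise_forward",
    "table1_report",
]

PREDICTORS_WK1 = ["lv_mass_wk1", "lv_edv_wk1", "lv_esv_wk1", "lv_ef_wk1", "is_wk1"]
OUTCOMES_WK4 = ["lv_mass_wk4", "lv_esv_wk4", "lv_edv_wk4", "lv_ef_wk4"]

_POSITIVE = ["lv_mass_wk1", "lv_edv_wk1", "lv_esv_wk1", "lv_mass_wk4", "lv_edv_wk4", "lv_esv_wk4"]
_PCT = ["lv_ef_wk1", "is_wk1", "lv_ef_wk4"]


def validate_cohort(cohort: pd.DataFrame, require_outcomes: bool = True) -> pd.DataFrame:
    """Validate the per-animal cohort schema and invariants.

    Requires ``subject_id`` (unique), ``group`` in {MI, sham}, positive
    volumes/masses and percentages in [0, 100]. Returns the frame unchanged.
    """
    required = ["subject_id", "group"] + PREDICTORS_WK1
    if require_outcomes:
        required += OUTCOMES_WK4
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise CohortSchemaError(f"cohort table missing column(s): {missing}")
    if cohort["subject_id"].duplicated().any():
        dupes = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].tolist()
        raise CohortSchemaError(f"duplicated subject_id(s): {dupes}")
    bad_groups = set(cohort["group"]) - {"MI", "sham"}
    if bad_groups:
        raise CohortSchemaError(f"unknown group value(s): {sorted(bad_groups)}")
    for col in _POSITIVE:
        if col in cohort.columns and (cohort[col] <= 0).any():
            raise CohortSchemaError(f"column {col} must be strictly positive")
    for col in _PCT:
        if col in cohort.columns and (
            (cohort[col] < 0).any() or (cohort[col] > 100).any()
        ):
            raise CohortSchemaError(f"column {col} must lie in [0, 100]")
    return cohort


def _fitting_rows(cohort: pd.DataFrame, mi_only: bool) -> pd.DataFrame:
    if mi_only and "group" in cohort.columns:
        cohort = cohort[cohort["group"] == "MI"]
    return cohort


def _pearson(x: np.ndarray, y: np.ndarray, name: str) -> tuple[float, float, int]:
    n = len(x)
    if n < 3:
        raise UndefinedCorrelationError(f"need >= 3 complete rows for {name}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(f"column {name} is constant")
    res = stats.pearsonr(x, y)  # two-sided p via the exact t-transform
    return float(np.clip(res.statistic, -1.0, 1.0)), float(res.pvalue), n


@dataclass
class CorrelationTable:
    """Pairwise (predictor, outcome) Pearson correlations with p and n."""

    table: pd.DataFrame  # columns: predictor, outcome, r, p, n

    def __post_init__(self) -> None:
        r = self.table["r"]
        if ((r < -1) | (r > 1)).any():
            raise CohortSchemaError("correlation outside [-1, 1]")

    def pivot(self, value: str = "r") -> pd.DataFrame:
        return self.table.pivot(index="predictor", columns="outcome", values=value)

    def best_predictors(self) -> pd.Series:
        """Per outcome, the predictor with the largest |r|."""
        idx = self.table.groupby("outcome")["r"].transform(lambda s: s.abs()).groupby(
            self.table["outcome"]
        ).idxmax()
        best = self.table.loc[idx].set_index("outcome")["predictor"]
        return best

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.table.to_dict(orient="records"), indent=2) + "\n"
        )

    @classmethod
    def from_records(cls, records: list[dict]) -> "CorrelationTable":
        return cls(pd.DataFrame(records)[["predictor", "outcome", "r", "p", "n"]])


def correlation_table(
    cohort: pd.DataFrame,
    predictors: list[str] | None = None,
    outcomes: list[str] | None = None,
    mi_only: bool = True,
    bonferroni: bool = False,
) -> CorrelationTable:
    """Univariate correlation of each predictor against each outcome.

    Pairwise-complete rows are used per cell; p-values are two-sided from
    the t-transform. ``bonferroni`` adds a corrected column (off by default:
    the univariate screen is reported uncorrected).
    """
    predictors = predictors or PREDICTORS_WK1
    outcomes = outcomes or OUTCOMES_WK4
    df = _fitting_rows(cohort, mi_only)
    rows = []
    for pred in predictors:
        for out in outcomes:
            sub = df[[pred, out]].dropna()
            r, p, n = _pearson(
                sub[pred].to_numpy(float), sub[out].to_numpy(float), f"{pred}~{out}"
            )
            rows.append({"predictor": pred, "outcome": out, "r": r, "p": p, "n": n})
    table = pd.DataFrame(rows)
    if bonferroni:
        table["p_bonferroni"] = np.minimum(table["p"] * len(table), 1.0)
    return CorrelationTable(table)


@dataclass
class RegressionFit:
    """Simple least-squares fit of one outcome on one predictor."""

    outcome: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n: int
    slope_se: float
    intercept_se: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CohortSchemaError(f"r² out of range: {self.r_squared}")

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "predictor": self.predictor,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "n": self.n,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
        }


def ols_fit(
    cohort: pd.DataFrame, outcome: str, predictor: str, mi_only: bool = True
) -> RegressionFit:
    """OLS regression of ``outcome`` on ``predictor`` over the MI rows."""
    df = _fitting_rows(cohort, mi_only)[[predictor, outcome]].dropna()
    x = df[predictor].to_numpy(float)
    y = df[outcome].to_numpy(float)
    n = len(x)
    if n < 2:
        raise CohortSchemaError(f"need >= 2 complete rows, got {n}")
    if np.ptp(x) == 0:
        raise CohortSchemaError(f"predictor {predictor} is constant (rank deficient)")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    dof = n - 2
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else 0.0
    r2 = float(res.rvalue**2)
    return RegressionFit(
        outcome=outcome,
        predictor=predictor,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        residual_sd=residual_sd,
        n=n,
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


@dataclass
class StepwiseStep:
    predictor: str
    partial_f: float
    p: float
    r_squared_after: float


@dataclass
class StepwiseResult:
    """Trace and final model of forward selection."""

    outcome: str
    steps: list[StepwiseStep]
    coefficients: dict[str, float]  # includes 'intercept'
    n: int
    entry_alpha: float

    @property
    def selected(self) -> list[str]:
        return [s.predictor for s in self.steps]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "entry_alpha": self.entry_alpha,
            "n": self.n,
            "steps": [
                {
                    "predictor": s.predictor,
                    "partial_f": s.partial_f,
                    "p": s.p,
                    "r_squared_after": s.r_squared_after,
                }
                for s in self.steps
            ],
            "coefficients": self.coefficients,
        }


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta, int(rank)


def stepwise_forward(
    cohort: pd.DataFrame,
    outcome: str,
    candidates: list[str] | None = None,
    entry_alpha: float = 0.05,
    mi_only: bool = True,
) -> StepwiseResult:
    """Forward selection by partial-F entry test.

    At each step every remaining candidate is added in turn to the current
    model; the one with the smallest partial-F p-value enters if p <
    ``entry_alpha`` (ties broken by candidate order). Entered variables are
    never removed. Candidates whose addition leaves the design rank
    deficient (duplicates, exact collinearity) are skipped with a warning.
    """
    candidates = list(candidates or PREDICTORS_WK1)
    cols = [outcome] + candidates
    df = _fitting_rows(cohort, mi_only)[cols].dropna()
    n = len(df)
    if n < len(candidates) + 2:
        raise CohortSchemaError(
            f"need >= {len(candidates) + 2} complete rows for "
            f"{len(candidates)} candidates, got {n}"
        )
    y = df[outcome].to_numpy(float)
    tss = float(np.sum((y - y.mean()) ** 2))

    selected: list[str] = []
    steps: list[StepwiseStep] = []
    X_cur = np.ones((n, 1))
    rss_cur, _, _ = _rss(X_cur, y)

    while True:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        best: tuple[float, int, str, float, float, np.ndarray] | None = None
        for order, cand in enumerate(remaining):
            X_try = np.hstack([X_cur, df[[cand]].to_numpy(float)])
            rss_try, _, rank = _rss(X_try, y)
            if rank < X_try.shape[1]:
                warnings.warn(
                    f"candidate {cand!r} is collinear with the current model; skipped",
                    stacklevel=2,
                )
                continue
            dof = n - X_try.shape[1]
            if dof <= 0:
                continue
            if rss_try <= 0:
                f_stat, p = np.inf, 0.0
            else:
                f_stat = (rss_cur - rss_try) / (rss_try / dof)
                p = float(stats.f.sf(f_stat, 1, dof))
            # ties broken by declared candidate order via the order key
            key = (p, order, cand, f_stat, rss_try, X_try)
            if best is None or key[:2] < (best[0], best[1]):
                best = key
        if best is None:
            break
        p, _order, cand, f_stat, rss_try, X_try = best
        if p >= entry_alpha:
            break
        selected.append(cand)
        X_cur = X_try
        rss_cur = rss_try
        r2_after = 1.0 - rss_cur / tss if tss > 0 else 0.0
        steps.append(
            StepwiseStep(
                predictor=cand,
                partial_f=float(f_stat),
                p=float(p),
                r_squared_after=float(r2_after),
            )
        )

    _, beta, _ = _rss(X_cur, y)
    coefficients = {"intercept": float(beta[0])}
    for i, name in enumerate(selected):
        coefficients[name] = float(beta[i + 1])
    return StepwiseResult(
        outcome=outcome,
        steps=steps,
        coefficients=coefficients,
        n=n,
        entry_alpha=entry_alpha,
    )


def plot_regression(
    cohort: pd.DataFrame,
    outcome: str,
    predictor: str,
    path: str | Path,
    mi_only: bool = True,
) -> RegressionFit:
    """Scatter of MI animals with the fitted line; sham animals, when
    present, appear as their group mean (open square). Saves PNG/SVG by
    file extension and returns the fit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = ols_fit(cohort, outcome, predictor, mi_only=mi_only)
    mi = _fitting_rows(cohort, mi_only)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.plot(mi[predictor], mi[outcome], "ko", ms=5, label="MI")
    xs = np.linspace(mi[predictor].min(), mi[predictor].max(), 50)
    ax.plot(xs, fit.predict(xs), "k-", lw=1)
    if "group" in cohort.columns and (cohort["group"] == "sham").any():
        sham = cohort[cohort["group"] == "sham"]
        ax.plot(sham[predictor].mean(), sham[outcome].mean(), "ks",
                mfc="white", ms=8, label="sham mean")
    ax.set_xlabel(predictor)
    ax.set_ylabel(outcome)
    ax.set_title(
        f"{outcome} = {fit.slope:.2f}·{predictor} + {fit.intercept:.1f}"
        f"  (r² = {fit.r_squared:.2f})", fontsize=9)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return fit


def table1_report(
    cohort: pd.DataFrame, mi_only: bool = True
) -> tuple[CorrelationTable, pd.DataFrame]:
    """Full 5 × 4 predictor/outcome correlation table with the per-outcome
    best predictor (largest |r|) flagged.

    Returns the :class:`CorrelationTable` and a formatted wide frame with
    ``r (p)`` cells and ``*`` on the best predictor per outcome.
    """
    validate_cohort(cohort)
    ct = correlation_table(cohort, PREDICTORS_WK1, OUTCOMES_WK4, mi_only=mi_only)
    best = ct.best_predictors()

    def _cell(row: pd.Series) -> str:
        star = "*" if best[row["outcome"]] == row["predictor"] else ""
        return f"{row['r']:.2f}{star} (p={row['p']:.2g})"

    formatted = ct.table.assign(cell=ct.table.apply(_cell, axis=1)).pivot(
        index="predictor", columns="outcome", values="cell"
    )
    formatted = formatted.reindex(index=PREDICTORS_WK1, columns=OUTCOMES_WK4)
    return ct, formatted
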