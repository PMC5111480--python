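"""Quality-control checks for contour-based LV measurements.

Three accuracy checks accompany the volumetry: (i) the myocardial mass
computed independently at end-diastole and end-systole must agree (the wall
is incompressible, so a large discrepancy flags tracing error) — the
acceptance bound is a 5% relative difference; (ii) inter-observer agreement
on repeated analyses (Pearson r plus Bland-Altman mean difference and 95%
limits of agreement); (iii) correlation of MRI-derived mass against mass
weighed at autopsy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CineLVError, UndefinedCorrelationError
from .volumetry import VolumetryResult

__all__ = [
    "QCReport",
    "mass_agreement_check",
    "observer_agreement",
    "autopsy_correlation",
]

#: maximal tolerated ED/ES mass discrepancy, percent
DEFAULT_MASS_THRESHOLD_PCT = 5.0


def mass_agreement_check(
    result: VolumetryResult | tuple[float, float],
    threshold_pct: float = DEFAULT_MASS_THRESHOLD_PCT,
) -> tuple[float, bool]:
    """ED/ES mass discrepancy, percent, and whether it passes the bound.

    discrepancy = 100·|mass_ED − mass_ES| / mean(mass_ED, mass_ES); the
    symmetric denominator makes the check order-independent.
    """
    if isinstance(result, VolumetryResult):
        mass_ed, mass_es = result.mass_ed, result.mass_es
    else:
        mass_ed, mass_es = result
    if mass_ed <= 0 or mass_es <= 0:
        raise CineLVError("masses must be positive")
    discrepancy = 100.0 * abs(mass_ed - mass_es) / ((mass_ed + mass_es) / 2.0)
    return discrepancy, discrepancy <= threshold_pct


def observer_agreement(
    measurements_a: pd.DataFrame, measurements_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-variable agreement between two observers' measurement tables.

    Both tables must be indexed by subject and hold the same numeric
    variables. Returns, per variable: Pearson r, mean difference (a − b)
    and the 95% limits of agreement (mean ± 1.96 · SD of the differences).
    """
    if "subject_id" in measurements_a.columns:
        measurements_a = measurements_a.set_index("subject_id")
    if "subject_id" in measurements_b.columns:
        measurements_b = measurements_b.set_index("subject_id")
    if set(measurements_a.index) != set(measurements_b.index):
        raise CineLVError(
            "observer tables cover different subjects: "
            f"{sorted(set(measurements_a.index) ^ set(measurements_b.index))}"
        )
    common = [c for c in measurements_a.columns if c in measurements_b.columns]
    if not common:
        raise CineLVError("observer tables share no variables")
    b = measurements_b.loc[measurements_a.index]

    rows = []
    for col in common:
        x = measurements_a[col].to_numpy(dtype=float)
        y = b[col].to_numpy(dtype=float)
        diff = x - y
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = 1.0 if np.allclose(diff, diff[0]) else np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        sd = float(np.std(diff, ddof=1)) if len(diff) > 1 else 0.0
        mean_diff = float(np.mean(diff))
        rows.append(
            {
                "variable": col,
                "pearson_r": r,
                "mean_difference": mean_diff,
                "loa_lower": mean_diff - 1.96 * sd,
                "loa_upper": mean_diff + 1.96 * sd,
                "n": len(diff),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def autopsy_correlation(
    calculated_mass: np.ndarray | pd.Series, measured_mass: np.ndarray | pd.Series
) -> float:
    """Pearson r between MRI-calculated and autopsy-weighed LV mass."""
    x = np.asarray(calculated_mass, dtype=float)
    y = np.asarray(measured_mass, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CineLVError("paired 1-D mass vectors required")
    if len(x) < 3:
        raise UndefinedCorrelationError("need >= 3 paired mass values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant masses")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class QCReport:
    """Bundle of the three checks for one study (observer/autopsy optional)."""

    subject_id: str
    timepoint: str
    mass_discrepancy_pct: float
    mass_check_pass: bool
    mass_threshold_pct: float = DEFAULT_MASS_THRESHOLD_PCT
    observer_agreement: pd.DataFrame | None = field(default=None, repr=False)
    autopsy_r: float | None = None

    @classmethod
    def from_volumetry(
        cls,
        result: VolumetryResult,
        threshold_pct: float = DEFAULT_MASS_THRESHOLD_PCT,
    ) -> "QCReport":
        disc, ok = mass_agreement_check(result, threshold_pct)
        return cls(
            subject_id=result.subject_id,
            timepoint=result.timepoint,
            mass_discrepancy_pct=disc,
            mass_check_pass=ok,
            mass_threshold_pct=threshold_pct,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subject_id": self.subject_id,
            "timepoint": self.timepoint,
            "mass_discrepancy_pct": self.mass_discrepancy_pct,
            "mass_check_pass": bool(self.mass_check_pass),
            "mass_threshold_pct": self.mass_threshold_pct,
            "autopsy_r": self.autopsy_r,
        }
        if self.observer_agreement is not None:
            payload["observer_agreement"] = self.observer_agreement.reset_index().to_dict(
                orient="records"
            )
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
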