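"""Infarct sizing from marked akinetic arcs at end-diastole.

Mature infarct scar appears as thinned, akinetic wall on cine MRI. Its
extent is quantified per short-axis slice as the mean of the epicardial and
endocardial akinetic arc fractions, averaged over all traced slices:

    infarct size (%) = 1/NSLICES · Σ_slices ½ (I_epi/T_epi + I_endo/T_endo) × 100

where I is the summed marked arc length and T the border circumference of
that slice at the end-diastolic phase. NSLICES counts every traced LV slice
by default (slices without marked arcs contribute zero); counting only
infarct-containing slices is available behind ``only_infarcted_slices``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .contours import Border, CineStudy
from .errors import CineLVError, InfarctMarkingError
from .volumetry import detect_ed_es

__all__ = ["InfarctResult", "infarct_size", "infarct_report"]


@dataclass
class InfarctResult:
    """Per-slice arc measurements and the overall infarct percentage."""

    subject_id: str
    timepoint: str
    ed_phase: int
    per_slice: pd.DataFrame  # slice_index, i_ep, t_ep, i_en, t_en, slice_fraction
    n_slices: int
    infarct_pct: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.infarct_pct <= 100.0):
            raise CineLVError(f"infarct_pct out of [0, 100]: {self.infarct_pct}")


def infarct_size(
    study: CineStudy,
    ed_phase: int | None = None,
    only_infarcted_slices: bool = False,
) -> InfarctResult:
    """Compute the infarct-size statistic from arcs marked on the
    end-diastolic tracings.

    Raises :class:`InfarctMarkingError` when arcs exist in the study but
    none on the ED phase — the statistic is defined at end-diastole, so the
    marking must be placed there.
    """
    if ed_phase is None:
        ed_phase, _ = detect_ed_es(study)

    def _has_arcs(phase: int) -> bool:
        return any(
            study.get(sl, phase, b).infarct_arcs
            for sl in study.slices
            for b in (Border.EPICARDIAL, Border.ENDOCARDIAL)
        )

    if not _has_arcs(ed_phase) and any(
        _has_arcs(ph) for ph in study.phases if ph != ed_phase
    ):
        raise InfarctMarkingError(
            f"infarct arcs are marked only on non-ED phases; mark them on the "
            f"end-diastolic tracings (detected ED phase {ed_phase})"
        )

    rows = []
    for sl in study.slices:
        epi = study.get(sl, ed_phase, Border.EPICARDIAL)
        endo = study.get(sl, ed_phase, Border.ENDOCARDIAL)
        i_ep, t_ep = epi.infarct_length(), epi.perimeter()
        i_en, t_en = endo.infarct_length(), endo.perimeter()
        frac = 0.5 * (i_ep / t_ep + i_en / t_en)
        rows.append(
            {
                "slice_index": sl,
                "i_ep_mm": i_ep,
                "t_ep_mm": t_ep,
                "i_en_mm": i_en,
                "t_en_mm": t_en,
                "slice_fraction": frac,
            }
        )
    table = pd.DataFrame(rows)
    if only_infarcted_slices:
        counted = table[table["slice_fraction"] > 0]
        if counted.empty:
            counted = table  # no infarct anywhere: 0% over all slices
    else:
        counted = table
    n_slices = len(counted)
    infarct_pct = 100.0 * counted["slice_fraction"].mean()
    return InfarctResult(
        subject_id=study.subject_id,
        timepoint=study.timepoint,
        ed_phase=ed_phase,
        per_slice=table,
        n_slices=n_slices,
        infarct_pct=float(infarct_pct),
    )


def infarct_report(
    result: InfarctResult,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> pd.DataFrame:
    """Tabular per-slice report; optionally written as CSV and/or JSON.

    The returned frame carries the overall percentage as an attribute-free
    extra column on every row so the CSV is self-contained.
    """
    table = result.per_slice.copy()
    table["subject_id"] = result.subject_id
    table["timepoint"] = result.timepoint
    table["infarct_pct_overall"] = result.infarct_pct
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "subject_id": result.subject_id,
            "timepoint": result.timepoint,
            "ed_phase": result.ed_phase,
            "n_slices": result.n_slices,
            "infarct_pct": result.infarct_pct,
            "per_slice": result.per_slice.to_dict(orient="records"),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    return table
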