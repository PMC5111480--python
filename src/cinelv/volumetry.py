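"""Slice-summation (Simpson's rule) LV volumetry from cine contour stacks.

Per slice and phase the cavity volume is endocardial area × slice thickness
and the myocardial volume is (epicardial − endocardial) area × thickness;
summing over contiguous slices gives the chamber and wall volumes. The
phases of maximal and minimal summed cavity volume define end-diastole and
end-systole; stroke volume, ejection fraction and LV mass follow:

    SV = EDV − ESV
    EF% = SV / EDV × 100
    mass = myocardial volume × 1.05 mg/mm³

with the reported mass the average of the ED- and ES-derived values.
1 mm³ and 1 μl are the same unit and are used interchangeably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .contours import Border, CineStudy
from .errors import CineLVError, PhaseError

__all__ = [
    "MYOCARDIAL_SPECIFIC_GRAVITY",
    "VolumetryResult",
    "myocardial_volume",
    "lv_mass",
    "cavity_volume",
    "detect_ed_es",
    "quantify",
]

#: myocardial specific gravity, mg per mm³
MYOCARDIAL_SPECIFIC_GRAVITY = 1.05


def _check_phase(study: CineStudy, phase: int) -> None:
    if phase not in study.phases:
        raise PhaseError(f"phase {phase} not present (phases: {study.phases})")


def myocardial_volume(study: CineStudy, phase: int) -> float:
    """Myocardial (wall) volume in mm³ at one phase: Σ_slices
    (epicardial − endocardial area) × slice thickness."""
    _check_phase(study, phase)
    total = 0.0
    for sl in study.slices:
        epi = study.get(sl, phase, Border.EPICARDIAL).area()
        endo = study.get(sl, phase, Border.ENDOCARDIAL).area()
        total += (epi - endo) * study.slice_thickness
    return total


def lv_mass(myocardial_volume_mm3: float) -> float:
    """Convert myocardial volume (mm³) to LV mass (mg) via the myocardial
    specific gravity of 1.05 mg/mm³."""
    if myocardial_volume_mm3 <= 0:
        raise CineLVError(
            f"myocardial volume must be > 0 mm³, got {myocardial_volume_mm3}"
        )
    return myocardial_volume_mm3 * MYOCARDIAL_SPECIFIC_GRAVITY


def cavity_volume(study: CineStudy, phase: int) -> float:
    """LV cavity volume in μl at one phase: Σ_slices endocardial area ×
    slice thickness (1 mm³ ≡ 1 μl)."""
    _check_phase(study, phase)
    return sum(
        study.get(sl, phase, Border.ENDOCARDIAL).area() * study.slice_thickness
        for sl in study.slices
    )


def detect_ed_es(study: CineStudy) -> tuple[int, int]:
    """End-diastolic and end-systolic phases: the phases of maximal and
    minimal summed cavity volume, ties broken toward the lowest phase index.
    """
    if study.n_phases < 2:
        raise PhaseError("ED/ES detection needs at least 2 phases")
    vols = {ph: cavity_volume(study, ph) for ph in study.phases}
    ed = min(ph for ph, v in vols.items() if v == max(vols.values()))
    es = min(ph for ph, v in vols.items() if v == min(vols.values()))
    return ed, es


@dataclass
class VolumetryResult:
    """Global function and mass measurements for one study.

    Volumes in μl, masses in mg, EF in percent. ``per_slice`` tabulates
    cavity volume (μl) and myocardial area (mm²) for every slice and phase.
    """

    subject_id: str
    timepoint: str
    edv: float
    esv: float
    sv: float
    ef: float
    mass_ed: float
    mass_es: float
    mass_avg: float
    ed_phase: int
    es_phase: int
    per_slice: pd.DataFrame

    def __post_init__(self) -> None:
        if not (self.edv >= self.esv >= 0):
            raise CineLVError(f"EDV ({self.edv}) must be >= ESV ({self.esv}) >= 0")
        if not (0 <= self.ef <= 100):
            raise CineLVError(f"EF must lie in [0, 100], got {self.ef}")
        if min(self.mass_ed, self.mass_es, self.mass_avg) <= 0:
            raise CineLVError("masses must be positive")

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "timepoint": self.timepoint,
            "edv_ul": self.edv,
            "esv_ul": self.esv,
            "sv_ul": self.sv,
            "ef_pct": self.ef,
            "mass_ed_mg": self.mass_ed,
            "mass_es_mg": self.mass_es,
            "mass_mg": self.mass_avg,
            "ed_phase": self.ed_phase,
            "es_phase": self.es_phase,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_csv_row(self) -> pd.DataFrame:
        """One-row summary frame (the cohort-assembly unit)."""
        d = self.to_dict()
        d.pop("mass_ed_mg")
        d.pop("mass_es_mg")
        return pd.DataFrame([d])


def quantify(study: CineStudy) -> VolumetryResult:
    """Full volumetric quantification of a cine study.

    Detects ED/ES, assembles EDV, ESV, SV = EDV − ESV, EF = SV/EDV × 100 and
    the ED-, ES- and averaged myocardial masses.
    """
    ed, es = detect_ed_es(study)
    edv = cavity_volume(study, ed)
    esv = cavity_volume(study, es)
    sv = edv - esv
    ef = 0.0 if edv == 0 else sv / edv * 100.0
    mass_ed = lv_mass(myocardial_volume(study, ed))
    mass_es = lv_mass(myocardial_volume(study, es))

    rows = []
    for ph in study.phases:
        for sl in study.slices:
            endo = study.get(sl, ph, Border.ENDOCARDIAL).area()
            epi = study.get(sl, ph, Border.EPICARDIAL).area()
            rows.append(
                {
                    "slice_index": sl,
                    "phase_index": ph,
                    "cavity_volume_ul": endo * study.slice_thickness,
                    "myocardial_area_mm2": epi - endo,
                }
            )

    return VolumetryResult(
        subject_id=study.subject_id,
        timepoint=study.timepoint,
        edv=edv,
        esv=esv,
        sv=sv,
        ef=ef,
        mass_ed=mass_ed,
        mass_es=mass_es,
        mass_avg=(mass_ed + mass_es) / 2.0,
        ed_phase=ed,
        es_phase=es,
        per_slice=pd.DataFrame(rows),
    )
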