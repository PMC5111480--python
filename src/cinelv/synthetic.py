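"""Synthetic ground-truthed data: a cine LV phantom and a cohort simulator.

Phantom
-------
The left ventricle is modelled as a half-ellipsoid cavity (radial semi-axis
``cavity_radius_mm``, long semi-axis ``cavity_length_mm``) wrapped in a
myocardial shell of ``wall_thickness_mm``, truncated at the basal plane and
sliced perpendicular to the long axis into contiguous short-axis slices.
Each slice/phase yields an epicardial and an endocardial polygon sampled at
the slice mid-plane. Over the cardiac cycle the endocardial radius scales by
a smooth periodic contraction profile; the epicardial radius follows so that
the wall cross-sectional area of every slice is conserved (incompressible
myocardium), which is what makes the ED/ES mass QC check pass by
construction.

An optional infarct is an angular wedge in which the wall is thinned by a
factor κ and the endocardial radius is frozen at its end-diastolic value
(akinetic scar neither contracts nor thickens). The transition between
infarcted and healthy sectors is smoothed over a few degrees so polygons
stay simple. Vertices inside the wedge carry the infarct flag, feeding the
arc-based infarct-size statistic.

Cohort
------
The cohort simulator emits a per-animal measurement table with the week-1
predictor set and week-4 outcomes. A latent infarct-severity draw drives
the week-1 variables; week-4 outcomes are linear functions of week-1
variables plus noise, with the EDV_wk4 ~ ESV_wk1 link defaulting to the
printed remodelling line (slope 1.33, intercept 26 μl). Sham animals sit
near healthy reference means. All generating coefficients are returned as
a ground-truth record.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate

from .contours import Border, CineStudy, ContourTracing
from .errors import SpecError
from .volumetry import MYOCARDIAL_SPECIFIC_GRAVITY

__all__ = [
    "InfarctSpec",
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "simulate_second_observer",
]


@dataclass
class InfarctSpec:
    """Angular wedge of thinned, akinetic wall.

    ``theta_start_deg``/``theta_extent_deg`` bound the wedge,
    ``slice_start``/``slice_stop`` the affected slices (half-open;
    ``slice_stop=None`` means all slices from ``slice_start``),
    ``thinning_factor`` κ ∈ (0, 1] scales the wall thickness, and
    ``transition_deg`` is the angular smoothing band at each boundary.
    """

    theta_start_deg: float = 0.0
    theta_extent_deg: float = 90.0
    slice_start: int = 0
    slice_stop: int | None = None
    thinning_factor: float = 0.6
    akinetic: bool = True
    transition_deg: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_extent_deg <= 360.0):
            raise SpecError("theta_extent_deg must lie in [0, 360]")
        if not (0.0 < self.thinning_factor <= 1.0):
            raise SpecError("thinning_factor must lie in (0, 1]")
        if self.transition_deg < 0:
            raise SpecError("transition_deg must be >= 0")


@dataclass
class PhantomSpec:
    """Parameters of the truncated-ellipsoid cine phantom.

    Defaults describe a mouse-sized LV: cavity semi-axes 2.1 × 7.0 mm
    (end-diastolic volume ≈ 65 μl), 1 mm wall, seven 1 mm slices, 20 cardiac
    phases and a peak radial contraction giving EF ≈ 60%. The contraction
    profile peaks at ``systole_fraction`` of the cycle (0.4 → end-systole at
    phase 8 of 20).
    """

    cavity_radius_mm: float = 2.1
    cavity_length_mm: float = 7.0
    wall_thickness_mm: float = 1.0
    n_slices: int = 7
    slice_thickness_mm: float = 1.0
    n_phases: int = 20
    contraction_fraction: float = 0.3675
    systole_fraction: float = 0.4
    infarct: InfarctSpec | None = None
    vertices_per_contour: int = 96
    observer_noise_sd: float = 0.0
    subject_id: str = "phantom"
    timepoint: str = "week1"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.infarct, dict):
            self.infarct = InfarctSpec(**self.infarct)
        for name in (
            "cavity_radius_mm",
            "cavity_length_mm",
            "wall_thickness_mm",
            "slice_thickness_mm",
        ):
            if getattr(self, name) <= 0:
                raise SpecError(f"{name} must be > 0")
        if not (0.0 < self.contraction_fraction < 1.0):
            raise SpecError("contraction_fraction must lie in (0, 1)")
        if not (0.0 < self.systole_fraction < 1.0):
            raise SpecError("systole_fraction must lie in (0, 1)")
        if self.n_phases < 2:
            raise SpecError("n_phases must be >= 2")
        if self.n_slices < 1:
            raise SpecError("n_slices must be >= 1")
        if self.vertices_per_contour < 8:
            raise SpecError("vertices_per_contour must be >= 8")
        last_mid = (self.n_slices - 0.5) * self.slice_thickness_mm
        if last_mid >= self.cavity_length_mm:
            raise SpecError(
                "slice stack extends past the cavity apex: reduce n_slices or "
                "slice_thickness, or lengthen the cavity"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomSpec":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PhantomTruth:
    """Analytic ground truth for a generated phantom (traced extent only)."""

    edv_ul: float
    esv_ul: float
    sv_ul: float
    ef_pct: float
    shell_volume_mm3: float
    mass_mg: float
    ed_phase: int
    es_phase: int
    infarct_angular_fraction: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


# ----------------------------------------------------------------------
# phantom geometry helpers


def contraction_profile(t: float, systole_fraction: float) -> float:
    """Smooth periodic activation in [0, 1]: 0 at t=0 (end-diastole), 1 at
    t=``systole_fraction`` (end-systole), back to 0 at t=1."""
    if t <= systole_fraction:
        return math.sin(0.5 * math.pi * t / systole_fraction) ** 2
    return math.sin(0.5 * math.pi * (1.0 - t) / (1.0 - systole_fraction)) ** 2


def _phase_scale(spec: PhantomSpec, phase: int) -> float:
    t = phase / spec.n_phases
    return 1.0 - spec.contraction_fraction * contraction_profile(
        t, spec.systole_fraction
    )


def _endo_radius_ed(spec: PhantomSpec, z: float) -> float:
    a_r, a_l = spec.cavity_radius_mm, spec.cavity_length_mm
    return a_r * math.sqrt(max(0.0, 1.0 - (z / a_l) ** 2))


def _epi_radius_ed(spec: PhantomSpec, z: float) -> float:
    a_r = spec.cavity_radius_mm + spec.wall_thickness_mm
    a_l = spec.cavity_length_mm + spec.wall_thickness_mm
    return a_r * math.sqrt(max(0.0, 1.0 - (z / a_l) ** 2))


def _wedge_weight(theta: np.ndarray, inf: InfarctSpec) -> np.ndarray:
    """Smoothstep membership of angles in the infarct wedge, 1 inside,
    0 outside, blended over ``transition_deg`` at each boundary."""
    if inf.theta_extent_deg >= 360.0:
        return np.ones_like(theta)
    half = math.radians(inf.theta_extent_deg) / 2.0
    centre = math.radians(inf.theta_start_deg) + half
    delta = math.radians(max(inf.transition_deg, 1e-9))
    d = half - np.abs((theta - centre + np.pi) % (2 * np.pi) - np.pi)
    u = np.clip((d + delta / 2.0) / delta, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _infarct_slices(spec: PhantomSpec) -> range:
    if spec.infarct is None:
        return range(0)
    stop = spec.infarct.slice_stop
    return range(spec.infarct.slice_start, spec.n_slices if stop is None else stop)


def _slice_radii(
    spec: PhantomSpec, slice_index: int, phase: int, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Endocardial/epicardial radius per vertex angle, plus infarct flags."""
    z = (slice_index + 0.5) * spec.slice_thickness_mm
    r_en0 = _endo_radius_ed(spec, z)
    r_ep0 = _epi_radius_ed(spec, z)
    s = _phase_scale(spec, phase)
    # healthy sector: cavity scales, wall area conserved
    r_en_h = s * r_en0
    r_ep_h = math.sqrt(r_ep0**2 - r_en0**2 + r_en_h**2)

    inf = spec.infarct
    in_range = inf is not None and slice_index in _infarct_slices(spec)
    if not in_range:
        n = len(theta)
        return np.full(n, r_en_h), np.full(n, r_ep_h), np.zeros(n, dtype=bool)

    wall_inf = inf.thinning_factor * (r_ep0 - r_en0)
    if wall_inf <= 0:
        raise SpecError("thinning leaves non-positive wall thickness")
    r_en_i = r_en0 if inf.akinetic else r_en_h
    r_ep_i = r_en_i + wall_inf
    w = _wedge_weight(theta, inf)
    r_en = w * r_en_i + (1.0 - w) * r_en_h
    r_ep = w * r_ep_i + (1.0 - w) * r_ep_h

    start = math.radians(inf.theta_start_deg)
    extent = math.radians(inf.theta_extent_deg)
    rel = (theta - start) % (2 * np.pi)
    eps = 1e-9
    flags = (rel <= extent + eps) | (np.abs(rel - 2 * np.pi) <= eps)
    if inf.theta_extent_deg >= 360.0:
        flags = np.ones_like(flags)
    return r_en, r_ep, flags


def _arcs_from_flags(flags: np.ndarray) -> list[tuple[int, int]]:
    arcs: list[tuple[int, int]] = []
    n = len(flags)
    i = 0
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            arcs.append((i, j))
            i = j
        else:
            i += 1
    return arcs


def generate_phantom(spec: PhantomSpec) -> tuple[CineStudy, PhantomTruth]:
    """Generate the contour stack of one phantom plus its analytic truth.

    Fully reproducible from ``spec.seed`` (vertex observer noise is the only
    stochastic element and defaults to zero).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    nv = spec.vertices_per_contour
    theta = 2.0 * np.pi * np.arange(nv) / nv

    tracings: list[ContourTracing] = []
    for sl in range(spec.n_slices):
        for ph in range(spec.n_phases):
            r_en, r_ep, flags = _slice_radii(spec, sl, ph, theta)
            for border, r in ((Border.ENDOCARDIAL, r_en), (Border.EPICARDIAL, r_ep)):
                verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
                if spec.observer_noise_sd > 0:
                    verts = verts + rng.normal(
                        0.0, spec.observer_noise_sd, size=verts.shape
                    )
                arcs = _arcs_from_flags(flags) if spec.infarct is not None else []
                tracings.append(
                    ContourTracing(
                        slice_index=sl,
                        phase_index=ph,
                        border=border,
                        vertices=verts,
                        infarct_arcs=arcs,
                    )
                )
    study = CineStudy(
        subject_id=spec.subject_id,
        timepoint=spec.timepoint,
        tracings=tracings,
        slice_thickness=spec.slice_thickness_mm,
    )
    return study, phantom_truth(spec)


def _cross_section_areas(spec: PhantomSpec, z: float, slice_index: int, phase: int):
    """Continuous (pre-polygonisation) cavity and wall area at depth z."""
    theta = np.linspace(0.0, 2.0 * np.pi, 2049)
    # reuse the discrete radius field on a dense angular grid
    r_en0 = _endo_radius_ed(spec, z)
    r_ep0 = _epi_radius_ed(spec, z)
    s = _phase_scale(spec, phase)
    r_en_h = s * r_en0
    r_ep_h = math.sqrt(r_ep0**2 - r_en0**2 + r_en_h**2)
    inf = spec.infarct
    if inf is None or slice_index not in _infarct_slices(spec):
        cavity = math.pi * r_en_h**2
        wall = math.pi * (r_ep_h**2 - r_en_h**2)
        return cavity, wall
    wall_inf = inf.thinning_factor * (r_ep0 - r_en0)
    r_en_i = r_en0 if inf.akinetic else r_en_h
    r_ep_i = r_en_i + wall_inf
    w = _wedge_weight(theta, inf)
    r_en = w * r_en_i + (1.0 - w) * r_en_h
    r_ep = w * r_ep_i + (1.0 - w) * r_ep_h
    cavity = 0.5 * float(np.trapezoid(r_en**2, theta))
    wall = 0.5 * float(np.trapezoid(r_ep**2 - r_en**2, theta))
    return cavity, wall


def phantom_truth(spec: PhantomSpec) -> PhantomTruth:
    """Analytic ground truth over the traced extent, by long-axis
    quadrature of the continuous cross-sections (independent of the polygon
    discretisation and of the slice mid-plane sampling)."""
    h = spec.slice_thickness_mm

    def cavity_at(phase: int) -> float:
        total = 0.0
        for sl in range(spec.n_slices):
            val, _ = integrate.quad(
                lambda z: _cross_section_areas(spec, z, sl, phase)[0],
                sl * h,
                (sl + 1) * h,
                limit=200,
            )
            total += val
        return total

    def wall_at(phase: int) -> float:
        total = 0.0
        for sl in range(spec.n_slices):
            val, _ = integrate.quad(
                lambda z: _cross_section_areas(spec, z, sl, phase)[1],
                sl * h,
                (sl + 1) * h,
                limit=200,
            )
            total += val
        return total

    scales = [_phase_scale(spec, p) for p in range(spec.n_phases)]
    ed_phase = int(np.argmax(scales))
    es_phase = int(np.argmin(scales))
    edv = cavity_at(ed_phase)
    esv = cavity_at(es_phase)
    shell = wall_at(ed_phase)
    frac = 0.0 if spec.infarct is None else spec.infarct.theta_extent_deg / 360.0
    return PhantomTruth(
        edv_ul=edv,
        esv_ul=esv,
        sv_ul=edv - esv,
        ef_pct=100.0 * (edv - esv) / edv,
        shell_volume_mm3=shell,
        mass_mg=shell * MYOCARDIAL_SPECIFIC_GRAVITY,
        ed_phase=ed_phase,
        es_phase=es_phase,
        infarct_angular_fraction=frac,
    )


# ----------------------------------------------------------------------
# cohort simulator


@dataclass
class CohortSpec:
    """Generating model of the longitudinal measurement cohort.

    A latent severity u ~ Uniform(severity_low, severity_high) per MI mouse
    (fraction of LV compromised) drives the week-1 variables::

        ESV_wk1  = esv1_intercept + esv1_slope·u + ε
        EDV_wk1  = ESV_wk1 + sv1_intercept + sv1_slope·ESV_wk1 + ε
        EF_wk1   = 100·(1 − ESV_wk1/EDV_wk1)
        mass_wk1 = mass1_intercept + mass1_slope·u + ε
        IS_wk1   = is1_intercept + is1_slope·u + ε

    and week-4 outcomes are linear in week-1 variables::

        EDV_wk4  = edv4_slope·ESV_wk1 + edv4_intercept + ε   (default 1.33·x + 26)
        ESV_wk4  = esv4_slope·ESV_wk1 + esv4_intercept + ε
        mass_wk4 = mass4_slope·ESV_wk1 + mass4_intercept + ε
        EF_wk4   = ef4_slope·EF_wk1 + ef4_intercept + ε

    Volumes in μl, masses in mg, EF/IS in percent. Sham animals are drawn
    around healthy reference means with small week-1 → week-4 drift.
    """

    n_mi: int = 25
    n_sham: int = 11
    seed: int = 0
    severity_low: float = 0.05
    severity_high: float = 0.60
    esv1_intercept: float = 12.0
    esv1_slope: float = 75.0
    esv1_sd: float = 2.0
    sv1_intercept: float = 26.0
    sv1_slope: float = 0.05
    sv1_sd: float = 2.0
    mass1_intercept: float = 88.0
    mass1_slope: float = 30.0
    mass1_sd: float = 3.0
    is1_intercept: float = 5.0
    is1_slope: float = 55.0
    is1_sd: float = 3.0
    edv4_slope: float = 1.33
    edv4_intercept: float = 26.0
    edv4_sd: float = 2.5
    esv4_slope: float = 1.25
    esv4_intercept: float = 4.0
    esv4_sd: float = 3.0
    mass4_slope: float = 1.1
    mass4_intercept: float = 62.0
    mass4_sd: float = 4.0
    ef4_slope: float = 0.85
    ef4_intercept: float = -8.0
    ef4_sd: float = 6.0
    sham_esv_mean: float = 15.0
    sham_esv_sd: float = 1.5
    sham_sv_mean: float = 30.0
    sham_sv_sd: float = 2.0
    sham_mass_mean: float = 85.0
    sham_mass_sd: float = 3.0
    sham_drift_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.n_mi < 3:
            raise SpecError("n_mi must be >= 3")
        if self.n_sham < 0:
            raise SpecError("n_sham must be >= 0")
        if self.severity_high < self.severity_low:
            raise SpecError("severity_high must be >= severity_low")
        for f in dataclasses.fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise SpecError(f"{f.name} must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSpec":
        return cls(**json.loads(Path(path).read_text()))


def _check_ef_physiology(spec: CohortSpec, rate_tol: float = 0.01) -> None:
    """Reject specs whose generating model puts more than ``rate_tol`` of
    EF values outside [0, 100]. The rate is estimated on a large internal
    sample with a fixed stream so the verdict depends only on the spec
    parameters, not on the particular cohort drawn."""
    rng = np.random.default_rng(np.random.SeedSequence(987654321))
    m = 20_000
    u = rng.uniform(spec.severity_low, spec.severity_high, m)
    esv1 = spec.esv1_intercept + spec.esv1_slope * u + rng.normal(0, spec.esv1_sd, m)
    sv1 = spec.sv1_intercept + spec.sv1_slope * esv1 + rng.normal(0, spec.sv1_sd, m)
    edv1 = esv1 + sv1
    ok = (esv1 > 0) & (edv1 > esv1)
    ef1 = np.where(ok, 100.0 * (1.0 - esv1 / np.where(ok, edv1, 1.0)), np.nan)
    ef4 = spec.ef4_slope * ef1 + spec.ef4_intercept + rng.normal(0, spec.ef4_sd, m)
    bad = (
        ~ok
        | (ef1 < 0) | (ef1 > 100)
        | (ef4 < 0) | (ef4 > 100)
    )
    rate = float(np.mean(bad))
    if rate > rate_tol:
        raise SpecError(
            f"generating model puts {100 * rate:.1f}% of EF values outside "
            "[0, 100]; reduce the noise SDs"
        )


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw one cohort table plus the ground-truth generating record.

    Raises :class:`SpecError` if the generating model implies more than 1%
    of EF values outside [0, 100] (impossible physiology); the rare
    out-of-range values a valid spec still produces are clipped to the
    bounds.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    u = rng.uniform(spec.severity_low, spec.severity_high, spec.n_mi)

    esv1 = spec.esv1_intercept + spec.esv1_slope * u + rng.normal(0, spec.esv1_sd, spec.n_mi)
    sv1 = spec.sv1_intercept + spec.sv1_slope * esv1 + rng.normal(0, spec.sv1_sd, spec.n_mi)
    edv1 = esv1 + sv1
    mass1 = spec.mass1_intercept + spec.mass1_slope * u + rng.normal(0, spec.mass1_sd, spec.n_mi)
    is1 = spec.is1_intercept + spec.is1_slope * u + rng.normal(0, spec.is1_sd, spec.n_mi)

    edv4 = spec.edv4_slope * esv1 + spec.edv4_intercept + rng.normal(0, spec.edv4_sd, spec.n_mi)
    esv4 = spec.esv4_slope * esv1 + spec.esv4_intercept + rng.normal(0, spec.esv4_sd, spec.n_mi)
    mass4 = spec.mass4_slope * esv1 + spec.mass4_intercept + rng.normal(0, spec.mass4_sd, spec.n_mi)

    if np.any(esv1 <= 0) or np.any(edv1 <= esv1):
        raise SpecError("generated MI volumes are unphysiological; reduce noise SDs")
    ef1 = 100.0 * (1.0 - esv1 / edv1)
    ef4 = spec.ef4_slope * ef1 + spec.ef4_intercept + rng.normal(0, spec.ef4_sd, spec.n_mi)

    mi = pd.DataFrame(
        {
            "subject_id": [f"mi{i:02d}" for i in range(spec.n_mi)],
            "group": "MI",
            "lv_mass_wk1": mass1,
            "lv_edv_wk1": edv1,
            "lv_esv_wk1": esv1,
            "lv_ef_wk1": ef1,
            "is_wk1": is1,
            "lv_mass_wk4": mass4,
            "lv_esv_wk4": esv4,
            "lv_edv_wk4": edv4,
            "lv_ef_wk4": ef4,
        }
    )

    frames = [mi]
    if spec.n_sham > 0:
        n = spec.n_sham
        s_esv1 = rng.normal(spec.sham_esv_mean, spec.sham_esv_sd, n)
        s_edv1 = s_esv1 + rng.normal(spec.sham_sv_mean, spec.sham_sv_sd, n)
        s_mass1 = rng.normal(spec.sham_mass_mean, spec.sham_mass_sd, n)
        drift = lambda x: x + rng.normal(0, spec.sham_drift_sd, n)  # noqa: E731
        s_esv4, s_edv4, s_mass4 = drift(s_esv1), drift(s_edv1), drift(s_mass1)
        s_ef1 = 100.0 * (1.0 - s_esv1 / s_edv1)
        s_ef4 = 100.0 * (1.0 - s_esv4 / s_edv4)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"sham{i:02d}" for i in range(n)],
                    "group": "sham",
                    "lv_mass_wk1": s_mass1,
                    "lv_edv_wk1": s_edv1,
                    "lv_esv_wk1": s_esv1,
                    "lv_ef_wk1": s_ef1,
                    "is_wk1": 0.0,
                    "lv_mass_wk4": s_mass4,
                    "lv_esv_wk4": s_esv4,
                    "lv_edv_wk4": s_edv4,
                    "lv_ef_wk4": s_ef4,
                }
            )
        )
    cohort = pd.concat(frames, ignore_index=True)

    _check_ef_physiology(spec)
    for col in ("lv_ef_wk1", "lv_ef_wk4", "is_wk1"):
        cohort[col] = cohort[col].clip(0.0, 100.0)

    truth = {
        "severity": u.tolist(),
        "coefficients": {
            k: getattr(spec, k)
            for k in (
                "esv1_intercept", "esv1_slope", "sv1_intercept", "sv1_slope",
                "mass1_intercept", "mass1_slope", "is1_intercept", "is1_slope",
                "edv4_slope", "edv4_intercept", "esv4_slope", "esv4_intercept",
                "mass4_slope", "mass4_intercept", "ef4_slope", "ef4_intercept",
            )
        },
        "noise_sds": {
            k: getattr(spec, k)
            for k in (
                "esv1_sd", "sv1_sd", "mass1_sd", "is1_sd",
                "edv4_sd", "esv4_sd", "mass4_sd", "ef4_sd",
            )
        },
        "seed": spec.seed,
    }
    return cohort, truth


def simulate_second_observer(
    study: CineStudy, jitter_sd: float, seed: int = 0
) -> CineStudy:
    """Emulate an independent second tracing by Gaussian vertex jitter.

    Each tracing pair is re-jittered (fresh draws) until the polygons stay
    simple and the endocardial area remains below the epicardial area, up to
    a retry cap; zero jitter returns an identical copy.
    """
    if jitter_sd < 0:
        raise SpecError("jitter_sd must be >= 0")
    if jitter_sd == 0:
        return CineStudy(
            subject_id=study.subject_id,
            timepoint=study.timepoint,
            tracings=list(study.tracings),
            slice_thickness=study.slice_thickness,
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    max_retries = 25
    tracings: list[ContourTracing] = []
    for sl in study.slices:
        for ph in study.phases:
            epi = study.get(sl, ph, Border.EPICARDIAL)
            endo = study.get(sl, ph, Border.ENDOCARDIAL)
            for attempt in range(max_retries):
                try:
                    new_epi = ContourTracing(
                        slice_index=sl,
                        phase_index=ph,
                        border=Border.EPICARDIAL,
                        vertices=epi.vertices
                        + rng.normal(0, jitter_sd, epi.vertices.shape),
                        infarct_arcs=list(epi.infarct_arcs),
                    )
                    new_endo = ContourTracing(
                        slice_index=sl,
                        phase_index=ph,
                        border=Border.ENDOCARDIAL,
                        vertices=endo.vertices
                        + rng.normal(0, jitter_sd, endo.vertices.shape),
                        infarct_arcs=list(endo.infarct_arcs),
                    )
                    if new_endo.area() < new_epi.area():
                        tracings.extend([new_epi, new_endo])
                        break
                except ValueError:
                    continue
            else:
                raise SpecError(
                    f"jitter {jitter_sd} mm too large to keep slice {sl}, phase "
                    f"{ph} valid after {max_retries} attempts"
                )
    return CineStudy(
        subject_id=f"{study.subject_id}_obs2",
        timepoint=study.timepoint,
        tracings=tracings,
        slice_thickness=study.slice_thickness,
    )
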