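# Methods

## Measurement model

All geometry lives in physical units (mm) in the short-axis imaging plane;
pixel-to-mm conversion is assumed to have happened at ingest. A tracing is
an implicitly closed simple polygon (the file dialect never repeats the
first vertex), and every derived quantity is computed from the polygon
itself: area by the shoelace formula, circumference and arc lengths by
summed Euclidean edges. Validation rejects degenerate and self-intersecting
polygons (simplicity is checked with shapely), enforces the
epicardial/endocardial pairing on every (slice, phase), strict containment
by area, a common phase set across slices and contiguous slice indices — a
missing slice inside the covered range is an error, not a silent gap,
because silent gaps corrupt slice-summation volumes.

Volumes follow the slice-summation (Simpson) rule: cavity volume is
endocardial area × slice thickness summed over slices, myocardial volume is
the epicardial–endocardial area difference summed the same way; 1 mm³ and
1 μl are treated as the same unit. LV mass is myocardial volume ×
1.05 mg/mm³ (myocardial specific gravity) and the reported mass is the mean
of the ED- and ES-derived values.

End-diastole and end-systole are defined **globally** as the phases of
maximal and minimal summed cavity volume, with ties broken toward the
lowest phase index. Per-slice extrema would allow different slices to pick
different phases and could make SV negative; the global definition matches
standard cine analysis and guarantees `SV ≥ 0` by construction. A flat
(non-contracting) cycle yields ED = ES and EF = 0 rather than an error.

## Infarct size

Scar is marked on the end-diastolic tracings as runs of flagged vertices.
Arc length is counted over the cyclic polygon: an edge contributes when
both endpoints are flagged. This makes the measure monotone in the marked
set, yields exactly the full circumference when every vertex is flagged,
and handles runs that wrap past the index origin. Per slice the infarct
fraction is `½(I_epi/T_epi + I_endo/T_endo)`; the overall percentage is the
mean over **all** traced slices (slices without marked arcs contribute
zero). Averaging only over infarct-containing slices would inflate small
apical infarcts; that alternative reading is available behind
`only_infarcted_slices=True` but is not the default. Multiple disjoint arcs
on one border are summed before dividing by the circumference. Marking arcs
only on non-ED phases raises an error directing the user to the ED phase,
since the statistic is defined at end-diastole.

## Quality control

The ED/ES mass check uses the symmetric relative discrepancy
`100·|m_ED − m_ES| / mean(m_ED, m_ES)` against a 5% default bound; the
symmetric denominator makes pass/fail independent of argument order. The
check only flags — it never silently excludes a study. Observer agreement
reports per-variable Pearson r plus Bland–Altman mean difference and 95%
limits of agreement (mean ± 1.96·SD of differences), because r alone cannot
detect a systematic bias. The autopsy check is a plain Pearson r over
paired calculated/weighed masses.

## Remodelling statistics

Correlation p-values are two-sided via the exact t-transform
`t = r√(n−2)/√(1−r²)` (scipy's `pearsonr`). Simple regression goes through
`scipy.stats.linregress`, which supplies the coefficient standard errors;
residual SD uses n−2 degrees of freedom. Stepwise forward selection enters,
at each step, the candidate with the smallest partial-F p-value while that
p-value is below `entry_alpha` (default 0.05), with ties broken by declared
candidate order; there is no removal step. Candidates whose addition leaves
the design rank-deficient (duplicates, exact collinearity) are skipped with
a warning. With a single candidate the partial F reduces exactly to the
squared slope t of the simple regression, so the entry decision coincides
with the simple-regression test.

Sham-operated animals are carried in the cohort table but excluded from all
fitting by default: remodelling is a property of the infarcted group, and
mixing the tight sham cluster into the regression would inflate every
correlation. No multiple-testing correction is applied across the 5 × 4
correlation table by default (the univariate screen is reported raw); a
Bonferroni column can be switched on.

## Cine phantom

The LV is a half-ellipsoid cavity (radial semi-axis `a_r` = 2.1 mm, long
semi-axis `a_l` = 7.0 mm, EDV = ⅔πa_r²a_l ≈ 64.7 μl) inside a shell of
wall thickness 1 mm, truncated at the basal plane and cut into 7 contiguous
1 mm short-axis slices sampled at their mid-planes; polygons have 96
vertices. The defaults mirror the acquisition geometry the pipeline is
meant for (1 mm slices, ≥ 20 phases per cycle) at a mouse-like scale; the
slice stack is constrained to end before the cavity apex so no traced
cross-section degenerates.

Contraction scales the endocardial radius by `s(p) = 1 − c·g(p)` with a
smooth piecewise-sinusoidal activation `g` that is 0 at phase 0 and peaks
at 40% of the cycle, so with 20 phases end-systole falls at phase 8 —
systole occupying the first ~40% of the cycle is physiological. The default
peak contraction `c = 0.3675` gives `EF = 1 − (1−c)² ≈ 60%`. The epicardial
radius follows as `r_epi = √(r_epi,ED² − r_endo,ED² + r_endo²)`, which
conserves the wall cross-sectional area of every slice exactly
(incompressible myocardium). Because the polygon area of a regular n-gon is
a fixed multiple of r², the *measured* wall area is conserved exactly too —
this is why the ED/ES mass QC check passes with essentially zero
discrepancy on the phantom.

An infarct is an angular wedge (default 90°, thinning factor κ = 0.6) in
which the endocardial radius is frozen at its ED value across phases
(akinetic scar) and the wall thickness is multiplied by κ with no
compensatory thickening. The transition between sectors is blended with a
smoothstep over 10° at each boundary — a numerical necessity to keep
polygons simple. Vertices with angles inside the closed wedge are flagged
as infarcted. With the default 96-vertex grid a 90° wedge aligns with
vertex angles, and the endocardial arc fraction is exactly 25% at ED; the
epicardial fraction is slightly below 25% because the thinned sector has a
shorter arc, so the reported infarct size for a 90° wedge sits near 24%.

Ground truth (EDV, ESV, EF, shell volume, mass) is computed by adaptive
quadrature along the long axis of the *continuous* cross-sections —
independent of both the polygon discretisation and the slice mid-plane
sampling. At the defaults the traced measurement differs from truth by
≈ 0.2%: a +0.26% mid-plane (midpoint-rule) bias minus a −0.07%
polygon-inscription deficit. Convergence properties are therefore checked
against oracles that isolate one error source at a time: slice refinement
against a long-axis quadrature of the *polygonal* cross-section, vertex
refinement against the analytic circle area of a single cross-section.

## Cohort simulator

Each infarcted animal draws a latent severity `u ~ Uniform(0.05, 0.60)`
(fraction of LV compromised) that drives the week-1 variables, and week-4
outcomes are linear in week-1 variables plus Gaussian noise; the
EDV_wk4 link defaults to `1.33·ESV_wk1 + 26 μl`. Defaults were chosen once
to give mouse-scale values (week-1 ESV ≈ 16–57 μl, EF ≈ 34–63%, mass ≈
88–106 mg, infarct size ≈ 8–38%) and correlation strengths of the order
seen in post-MI cohorts (volume/mass outcomes driven by week-1 ESV at
r ≈ 0.95–0.99; week-4 EF driven by week-1 EF at r ≈ 0.75). Week-1 EF is
computed from the generated volumes, so it carries some variance
independent of severity; week-4 EF is generated from week-1 EF directly,
which makes EF the one outcome whose best predictor is EF itself rather
than ESV — the qualitative structure the prediction analysis is meant to
recover. Sham animals sit near healthy reference means (ESV 15 μl,
SV 30 μl, mass 85 mg) with small week-1 → week-4 drift and infarct size 0.

A spec whose generating model implies more than 1% of EF values outside
[0, 100] is rejected as impossible physiology. The rate is estimated on a
20,000-draw internal sample with a fixed RNG stream so the verdict depends
only on the spec parameters, not on the particular cohort drawn; the rare
out-of-range values a valid spec still produces (a few per ten thousand)
are clipped to the bounds.

The second-observer simulator adds independent Gaussian jitter to every
vertex and re-draws any (slice, phase) pair whose polygons become
self-intersecting or lose containment, up to a retry cap. Vertex jitter of
0.05 mm (a plausible manual re-tracing scale; the true magnitude for murine
tracings is not established, and this default is an order-of-magnitude
choice) perturbs global volumes by well under 1%.

All randomness flows from a single integer seed per spec through
`numpy` `SeedSequence` streams, so every generated file is byte-reproducible.

## Numerical choices

* Contour files store coordinates at 6 decimal places (1 nm) — far below
  tracing noise — and rows in a fixed sort order, so write∘read is the
  identity on files and read∘write is the identity on the data model to
  that precision.
* ED/ES ties break toward the lowest phase index; stepwise ties break by
  declared candidate order.
* Pearson r is clipped to [−1, 1] against floating-point overshoot;
  correlations of constant columns raise a named error rather than
  returning NaN.
* Degenerate inputs fail loudly: single-phase studies, non-positive
  volumes/masses, empty studies, sham-only cohorts.

## Validation scale and what it shows

The test suite validates on a 7-slice × 20-phase phantom (with 14 × 0.5 mm
and 28 × 0.25 mm refinements), cohorts of 25 infarcted + 11 sham animals,
and Monte-Carlo loops of 500–1000 replicates for the statistical operating
characteristics (type-I error of the correlation test, forward-selection
behaviour under signal and null, OLS bias and standard-error calibration).
These sizes keep the whole suite within a few tens of seconds on one CPU.

Passing these tests shows that the geometry, the volumetric formulas, the
infarct statistic and the statistics behave correctly on data whose ground
truth is known. It does **not** show that the pipeline is accurate on real
cine MRI: the phantom has circular cross-sections, no papillary muscles, no
trabeculation, no through-plane motion, no basal outflow-tract geometry and
no segmentation ambiguity, and the cohort simulator's non-headline link
coefficients are illustrative rather than empirical. Known limitations:
no papillary-muscle convention, no regional wall-motion scoring, no
transmurality grading, and the pipeline quantifies exactly the slices that
were traced — it cannot detect that a base or apex was left untraced.
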