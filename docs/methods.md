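# Methods

## The trial setting

Patient-derived xenograft (PDX) trials transplant patient tumor fragments
subcutaneously into immunodeficient mice; every "model" is the set of
tumors derived from one patient, and every model contributes several mice
(and up to two implant sites per mouse) to each treatment arm. Tumors are
enrolled when they reach roughly 200 mm³ and measured twice weekly with
calipers. The package implements the full analytic chain for such a trial:
volume computation, response grading, resistance detection, treatment
protocol logic, arm-level statistics, and a generative model of the data.

## Volume and growth curves

Volume uses the standard ellipsoid approximation V = L·W²/2 (mm³) from the
caliper length and width. Calipers are orientation-agnostic, so readings
are canonicalized to L ≥ W (swapped with a warning rather than rejected).
Growth curves are expressed relative to the baseline volume at treatment
start: the day-0 measurement, or the latest reading within the three days
before it (enrollment precedes the first dose by at most a few days).
Model-level curves average relative volumes across tumors by *exact*
measurement day — the twice-weekly schedule is a shared grid, so no
smoothing or interpolation enters the mean — with SEM computed from the
n−1 sample SD and reported as 0 when a single tumor remains. A tumor taken
off study (size limit or animal health) contributes through its removal
day and then simply drops out of the per-day mean; no carry-forward.

Evaluation days (28 and 59 in this design) rarely coincide with a caliper
day. The evaluation uses the nearest measured point within ±3 days, ties
broken toward the earlier day; if the window is empty the value is
linearly interpolated between the bracketing measurements, and if there is
no bracket the curve is reported as unevaluable rather than silently
graded.

## Response grading

Grading is a mouse-adapted RECIST analogue on relative volume: CR if the
volume at evaluation is at or below a detectability cut-off (default
0 mm³, configurable since "undetectable on inspection" has no numeric
definition); otherwise PD if the relative change reached ≥ +20% at two
*consecutive* measurement days on or before the evaluation day (the
confirmation rule protects against single noisy calipers; the onset is the
second confirming day); otherwise PR at ≤ −30%; otherwise SD. The +20%
boundary is treated as inclusive and configurable — published wording is
ambiguous between "more than 20%" and "≥ +20%", and the choice only moves
curves sitting exactly on the boundary.

A curve that ends before the evaluation window (early size-limit removal)
but whose progression is already confirmed is graded PD; this matches how
removed progressors are counted in practice.

Primary resistance is a PD call at the initial (day-28) evaluation.
Secondary resistance (SR) is initial disease control (SD or PR at day 28)
followed by progression, using the *same* confirmed two-point criterion
established after day 28. The confirmation requirement for SR is a design
choice — the one-sentence SR definition omits it — made for consistency
with the PD rule and robustness to caliper noise; a strict single-point
mode is available via `confirm=False`. Time to progression is the first
confirmed PD day, censored at end of study.

Response calls are computed both per tumor and per model mean, because
individual tumors can depart from their cohort's mean response; arm-level
aggregation tallies categories and the disease-control rate
(CR+PR+SD)/n, with display percentages rounded half away from zero. In
the bundled trial summary, the day-59 label "SR" counts as progression
and "missing" cells (models whose observation ended earlier) are dropped,
never imputed. The lasting-response rate at day 59 is reported over all
19 enrolled models, matching how the trial reported it.

## Intermittent treatment protocol

The long-term schedule is a small state machine fed observations in day
order: treatment starts at day 0; if the tumor is in PR at the day-59
evaluation, dosing pauses; it resumes when the tumor regrows to the
enrollment size (200 mm³); in re-treatment cycles the response is graded
against the volume at that cycle's own start (re-anchoring is a design
choice — the reference baseline for later cycles is not otherwise
defined, and observed courses show within-cycle volume reductions), and
after 30 days of continuous disease control dosing pauses again; the next
cycle starts when the volume reaches `doubling_factor` (default 2.0, the
quantification of "roughly doubled") times the volume at the previous
cycle's end. At most `max_cycles` (default 3) cycles run. Confirmed
progression while *on* treatment in a re-treatment cycle raises the
SR-under-intermittent flag and stops the run. The machine audits recorded
courses and, coupled to the simulator, runs closed-loop: dosing between
measurement days follows the state after the previous observation.

## The synthetic cohort generator

Each tumor is a two-compartment exponential mixture: a sensitive clone
growing at g_s per day that treatment suppresses at kill rate k, and a
resistant clone of initial fraction ρ₀ growing at g_r regardless:

    V(t) = (1−ρ₀)·V₀·exp(g_s·t − k·T_on(t)) + ρ₀·V₀·exp(g_r·t)

solved exactly piecewise over the treatment on/off intervals, so with zero
noise the simulated volumes equal the closed form to machine precision.
This is deliberately the simplest mechanism producing all observed
phenotypes: sustained PR (k > g_s, ρ₀ = 0), SD (k ≈ g_s), primary
resistance with delayed progression (moderate ρ₀: total volume plateaus
~2–3 weeks while the shrinking sensitive clone masks the expanding
resistant one), and SR (small ρ₀ emerging after initial response). Gompertz
or logistic saturation is intentionally omitted; tumors leave the study at
the 1500 mm³ size limit before saturation matters.

Observed volume is the true volume times lognormal noise with unit mean
and coefficient of variation `cv_noise` (default 0.1); the noisy volume is
back-converted to a caliper pair under a fixed length:width ratio of 1.25,
keeping the noise model one-parameter and guaranteeing L ≥ W. Enrollment
volumes are Normal(200, 15) mm³ truncated to ±30.

Default cohort design mirrors the study conditions: 19 models with a
9 PR / 5 SD / 5 PD phenotype mix, control and combination arms, 5–6 mice
per arm with 1–2 implant sites, twice-weekly measurements (alternating
3/4-day gaps) to day 59. Phenotype priors are invented calibration
constants, not fitted values: g_s is lognormally jittered around
0.08/day per model; k = 2·g_s for responders, k = g_s for SD, ρ₀ ∈
[0.25, 0.40] with g_r = g_s for primary resistance, and ρ₀ ∈ [10⁻³, 10⁻²]
with g_r = 0.12/day for SR-capable tumors. The faster resistant-clone rate
for the SR prior is deliberate: with g_r = g_s, fractions below ~1.5% can
not cross the +20% line inside the 59-day follow-up, so the SR phenotype
would be unobservable in-window. Monotherapy arms apply half the
combination kill rate — a phenomenological choice reflecting the weaker
single-agent effect, with no claim of biological fidelity. All randomness
derives from a single master seed; each tumor gets an independent
counter-derived stream, so identical seeds give byte-identical cohorts.

What the generator does *not* emulate: growth-rate drift over time,
correlated noise between the two implant sites of one mouse, inter-arm
baseline imbalance, animal-health dropouts (only size-limit removals are
generated), and any molecular layer. Passing recovery tests therefore
shows the classifier is consistent with the generator's assumptions, not
that it is robust to every artifact of real caliper data. One such gap is
visible within the simulation itself: for flat (SD-phenotype) tumors at
10% caliper noise, two consecutive +20% noise excursions occasionally
produce spurious SR calls — progression detection in tumors hovering at
baseline is noise-limited, which is exactly why the PD rule demands
confirmation and why SR detection inherits it.

## Statistics

Arm comparisons use the classical two-sided unpaired Student t-test on
relative volumes at a day (pooled variance by default, Welch by flag),
with the usual star convention (* p<0.05, ** p<0.01, *** p<0.001) and
p < 0.05 as the significance line. No multiple-testing correction is
applied across time points — a known limitation, kept for comparability
with common practice in these trials. Identical groups are reported as
t = 0, p = 1 by convention.

The qPCR expression ratio follows the Pfaffl efficiency-corrected form
E_target^ΔCt(target) / E_ref^ΔCt(ref); multiple housekeeping references
combine by geometric mean of expression, i.e. arithmetic mean on the Ct
scale, and the multi-reference combiner reduces exactly to the single-gene
case (the study's setting: GUSB). Amplification efficiencies default to
2.0 (perfect doubling) with a config override, since assay-specific
efficiencies are typically unreported. Triplicate Ct readings are averaged
arithmetically before the ratio. Densitometry fold change normalizes band
intensity by the geometric mean of the loading controls (beta-actin,
GAPDH) in each lane before taking the treated/control ratio.

## Problem sizes and numerical choices

The test suite and the acceptance script use the study-scale defaults: the
19-model cohort (~300 tumors), 200 tumors for the PR-recovery experiment,
60 tumors per point of the 4-point ρ₀ grid for SR monotonicity, and the
exhaustive 9 330-curve set (six relative-volume levels, up to six time
points) for the dual-route classifier check. Everything runs in seconds.
Thresholds are compared inclusively (≥ +20%, ≤ −30%) in exact floating
point; grid relative volumes like 1.25 are representable, so no epsilon is
needed in the dual-route comparison. Ties in evaluation-day lookup break
toward the earlier day; degenerate inputs (empty curves, baseline-only
courses, n = 1 SEM, unevaluable days) raise or warn explicitly rather than
defaulting.
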