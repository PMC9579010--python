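# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the limitations of `numerotune`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Stimulus protocols

**Numerosity localizer.**  Dot displays of 1–7 dots are presented every
650 ms (300 ms on, 350 ms blank), six presentations per numerosity
(3900 ms epochs), in an ascending sweep, a 20-dot baseline stretch,
a descending sweep and a second baseline, the whole sequence repeated four
times per run.  The baseline length is a free design parameter, set to six
epochs (23 400 ms).  About 10% of presentations show white instead of black
dots and carry an attention flag.  Dot placement is rejection sampling,
uniform over the circular field, with dots rejected if they cross the field
boundary or come within 10% of a radius of touching another dot; 10 000
rejected candidates raise a placement error.  Displays either hold the
total dot surface area constant across numerosities (default: the area of
a 0.4°-equivalent dot times a baseline factor of 20, so the 20-dot baseline
display has 0.4°-scale dots) or hold the individual dot size constant.

**Block design.**  Six categories — natural images with 1–3 main objects,
natural images with 10–42 objects, natural scenery, and dot analogues
(1–3, 20, 10–42 dots) — in 15 s blocks of 30 stimuli (300 ms on / 200 ms
off), each block followed by 15 s rest, each category twice per run in
seeded-random order.  Blocks draw 30 items without replacement from
per-category pools (natural pools: 93 one-object, 95 two-object, 70
three-object, 70 high-numerosity, 61 scenery images).  Runs carry a 12 s
lead-in and 12 s tail of rest so one run spans 384 s = 256 TRs of 1.5 s,
of which the first 8 are discarded (248 retained) — the lead-in is exactly
consumed by the discarded frames.

**High-numerosity counts.**  Only the first two moments of the
high-numerosity annotation distribution are specified (mean 19.42,
SD 8.8 on 10–42).  A log-normal truncated to [10, 42] cannot reach that
SD (truncation caps it near 8.5), so counts are drawn from the
maximum-entropy distribution on the integer support under the two moment
constraints, `p_k ∝ exp(a·k + b·k²)` with (a, b) solved numerically; the
resulting distribution matches both moments exactly and decays smoothly
from 10 to 42.

**Fixture images.**  Stand-ins for natural photographs are random-phase
textures whose Fourier amplitude is proportional to 1/f — the canonical
natural-image statistic — with `n` Gaussian-profile high-contrast blobs
(SD 3% of image side, contrast 0.3 of background SD, random sign) inserted
as countable "objects"; scenery fixtures are blob-free texture.  The blob
contrast is modest by construction so the composite spectrum keeps its 1/f
slope (verified by the spectrum tests).  The radially averaged amplitude
spectrum uses 16 log-spaced frequency bins from 2 cycles/image to Nyquist
and a least-squares line in log-log space; at least 8 populated bins are
required for a fit.

## BOLD simulator

Every voxel belongs to one of four kinds.  Numerosity-tuned voxels respond
to an event of numerosity *n* with `A·exp(−(ln n − ln μ)²/(2σ²))`.
Real cortical voxels mix neural populations, so tuned voxels may carry an
additional nonspecific response (`visual_amplitude`) to every stimulus
event; scenery events, which have no countable objects, drive only this
component.  Scenery-responsive voxels respond to the three natural-image
categories only; untuned visually responsive voxels to every event; null
voxels never.

Neural event trains are built as 50 ms boxcars — fine enough that the
300/650 ms stimulus asynchronies fall on the grid — convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1 s,
undershoot ratio 1/6, 32 s kernel) and averaged within each 1.5 s TR
window.  Internally the kernel is scaled to unit area, so a sustained unit
neural drive converges to a unit percent-signal plateau and voxel
amplitudes are in percent-signal units.  The same code path produces
simulator output and model predictions, so a noiseless simulated voxel is
fitted exactly.  Signals are placed on a baseline intensity of 1000 and
corrupted with AR(1) noise (lag-1 coefficient 0.3, marginal SD equal to
the configured white SD of 1.0% signal, stationary start) plus a per-run
linear drift with slope uniform in ±0.5%/run.

The default cohort has 7 subjects.  Six numerosity maps (NPC1–3, NTO, NPO,
NF) mix 50% tuned / 20% scenery-responsive / 20% untuned / 10% null voxels
(200 per ROI); V1 and LO are 90% untuned visual, PPA 90% scenery-responsive
(10% null each).  NF is present for 4 of the 7 subjects, matching the
between-subject variability of frontal maps.  Preferred numerosities are
log-uniform on [1, 7]; tuning widths follow σ = 0.3 + 0.25·ln μ with
Gaussian jitter (SD 0.05, floor 0.05) — a width-increasing-with-preferred
trend.  Tuned voxels' nonspecific component is uniform on [0, 1]% so the
scenery exclusion bites heterogeneously.  Each subject gets 4 localizer
runs and 7 block runs.

The tuned response amplitude is a free parameter of the simulation (the
study's real per-ROI amplitudes are not published numerically).  It is set
to 4.5% at sustained peak drive, which places single-voxel localizer
variance explained (on the 4-run average) in the 0.3–0.6 regime where the
selection threshold matters — 5th–95th percentiles ≈ 0.37–0.73 across the
tuned population — and was fixed from that design target, not tuned to any
test outcome.

## pRF estimation

The grid spans 25 log-spaced preferred numerosities on [1, 10] and 20
log-spaced widths on [0.05, 3] (natural-log units).  For each candidate the
amplitude and baseline are the OLS solution, so variance explained equals
the squared correlation between prediction and data; negative-amplitude
fits are assigned VE 0 (tuned responses are excitatory).  Refinement runs
Nelder–Mead on (ln μ, ln σ) within the grid bounds from the grid optimum
(the VE surface has curved μ–σ ridges on which quasi-Newton steps stall);
a refinement that fails to improve VE is discarded in favour of the grid
solution, so VE never decreases.  Baseline (20-dot) epochs enter the fit as
ordinary numerosity-20 events.  Localizer runs are averaged in
percent-signal units before fitting (the numerosity sequence is fixed by
the protocol, so run timing is identical).

**Selection.**  "Tuned to 1–3" means μ̂ in the closed interval [1, 3] and
VE ≥ 0.3.  A third criterion is applied by default: fits whose width sits
on the search bound are excluded, because an untuned visually responsive
voxel is exactly fitted by the σ → ∞ limit and otherwise enters the
selection with an arbitrary μ̂; width-at-bound exclusion is the standard
guard in pRF practice and is what keeps selection specificity above 0.9 on
the simulated cohort.  The rule actually applied is recorded in the
selection object.

## Block-design GLM

One regressor per category: the HRF-convolved train of that category's
300 ms presentations (nonzero only around its two blocks), peak-normalized
to 1, plus a constant and a linear drift per run.  Building the category
regressors from the event train rather than a 15 s boxcar keeps the design
on the same forward model as the simulator, so noiseless betas are exact;
after convolution the two parameterizations differ only in scale.  Runs
are concatenated with shared category columns and per-run nuisance columns,
which keeps degrees of freedom explicit.  Estimation is OLS; percent signal
change is 100 × beta / (mean per-run constant), which is invariant to
rescaling the raw signal.  No prewhitening is applied by default; under
AR(1) noise the nominal one-sided false-positive rate at t = 1.96 inflates
above 2.5%, and the test suite measures this rather than hiding it.

**Scenery exclusion.**  Voxels with scenery-versus-rest t < 1.96 are
excluded from the numerosity-map averages (t exactly 1.96 is retained, as
the rule excludes strictly smaller values); an unmasked parallel table is
always produced.  1.96 is applied as a one-directional cut, as specified.

## ROI statistics

The analysis unit is the subject: per subject, ROI and category, the mean
percent-signal beta over the relevant voxels (numerosity maps: tuned
selection ∩ scenery mask; control ROIs: all voxels).  The one-sided
Wilcoxon signed-rank test drops zero differences (counting them), assigns
midranks to ties, and computes exact p-values for n ≤ 25 by a dynamic
program over doubled midranks that is arithmetically identical to
enumerating all 2ⁿ sign assignments; above n = 25 a normal approximation
with continuity and tie correction is used.  Benjamini–Hochberg adjustment
is applied within one analysis family at a time — all ROI × category cells
of a positivity analysis, or all maps of the low-versus-high comparison —
since the original family definition is not documented more precisely;
both family choices are available.  The frontal maps are excluded from the
low-versus-high comparison: with 4 subjects the smallest attainable exact
p is 1/16 = 0.0625, so they cannot reach significance by construction —
the same power limitation reported for real frontal maps.

The untuned control configuration (`untuned_only=True`) replaces tuned and
scenery-responsive voxels by untuned ones; because the width-at-bound
exclusion then empties the tuned selection (correctly), the control
pipeline is run with the selection filter disabled so the null question —
does the inference manufacture a low-versus-high effect without tuning? —
is actually testable.

## Problem sizes

The default study conditions are used throughout: 7 subjects, 200
voxels/ROI, 4 localizer + 7 block runs.  The null-calibration checks use
10⁴ single-run white-noise voxels; the untuned-control null uses 30
replicates at 24 voxels/ROI and 3 block runs (ROI means are simply noisier
at the smaller voxel count; the inference operates identically).

## What the simulation does and does not show

The generator reproduces the structural properties the analysis depends
on: log-Gaussian tuning, mixed voxel populations, category-selective
control regions, 1/f image statistics with countable object annotations,
HRF dynamics, AR(1) noise and drifts, and the exact run geometry.  It does
not model retinotopy or topographic map structure, surface geometry,
motion or physiological artifacts, nonlinear BOLD summation, attentional
modulation, or the actual appearance of natural photographs (fixture
"objects" are Gaussian blobs).  Passing tests therefore validate the
*pipeline* — that each stage recovers what the generator put in, at
realistic noise levels — not the neuroscientific claim itself, which
requires real data.  Amplitudes per ROI are free parameters of the
simulation, so absolute percent-signal levels in the output tables are not
comparable to published figures; the significance patterns and directions
are the meaningful output.
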