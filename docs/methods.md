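# Methods

## Scope and data model

`opikin` computes objective performance indicators (OPIs) from robotic-console
kinematics for robotic Roux-en-Y gastric bypass (r-RYGB) and compares surgeon
cohorts per surgical step.  A case bundle holds four kinds of raw input:

* **kinematic streams** — timestamped 3-D positions (cm) of each hand's
  instrument tip and console wrist, one stream per (operator, hand, source);
* **activity intervals** — half-open spans `[start, end)` during which the
  console or a specific hand is actively driving;
* **step segments** — annotated spans with a raw label and the operating
  surgeon;
* **a roster** — operator → role (attending / fellow / resident), prior
  robotic case count, handedness.

Times are seconds from case start; coordinates live in an arbitrary fixed
right-handed frame.  Every metric is translation- and rotation-invariant, so
no registration across cases is attempted.  All intervals are half-open so
union/intersection/total-duration arithmetic is exact without boundary
double-counting.  The on-disk format is plain comma-separated text plus a
small YAML header, written with 17 significant digits so a write/read round
trip is bit-exact; the native recorder format of clinical consoles is
proprietary, so this layout is the package's interchange format.  Sampling
gaps beyond 5× the nominal period are logged, never fatal (clinical recorders
drop samples; the generator's inter-step idle gaps also surface here).

## Step ontology

Raw annotation labels are mapped case-insensitively through an extensible
lexicon onto eight canonical steps in procedural order: dissection, creation
of gastric pouch, measurement, division of mesentery, staple anastomosis,
enterotomy closure, defect closure, hand-sewn anastomosis.  Rare side tasks
(leak test, concurrent hiatal hernia repair) are excluded; unmapped labels
yield a distinct UNKNOWN outcome and are dropped with a warning.  Same-step
windows of one operator are unioned (a step revisited later is analyzed as
one unit — a configurable policy choice, since interruption structure is
genuinely ambiguous); windows are never merged across operators, so
per-operator OPIs stay computable within a step.  Overlap between different
steps' segments is resolved by delaying the later-starting segment to the end
of the earlier one, on the assumption of a linear ontology.  Steps with no
instrument-tip samples inside any window are omitted.

## OPI definitions and numerical choices

Per (case, step, operator):

* **Active times** are interval intersections of the scope's activity with
  the step windows.  When a bundle records only console-scope activity,
  per-hand activity is derived as spans where that hand's controller speed
  (smoothed over 0.1 s) exceeds 0.05 cm/s, intersected with console activity;
  both thresholds are configurable.
* **Path length** sums Euclidean distances between consecutive samples after
  clipping the tip stream to (hand-active ∩ step windows).  Clipping marks
  window boundaries as discontinuities and no distance is accumulated across
  them; no interpolation is performed at window edges.  Restricting travel to
  active time makes the identity *speed × active time = path length* exact by
  construction, matching a speed defined "during active console time".  The
  activity-unrestricted within-window path length is kept as a secondary
  field for sensitivity analyses.
* **Bimanual dexterity** is the dominant/non-dominant path-length ratio.
  Hand labels are carried on the streams; the roster's handedness field
  records the (here always right-handed) dominant side.
* **Workspace volume** is the convex hull (Qhull) of pooled both-hand tip
  positions within console-active spans of the step.  "Volume of space
  occupied" admits several readings; the convex hull is the simplest
  defensible one, and the package's Monte-Carlo inclusion oracle bounds its
  numerical behavior.  Fewer than 4 points or a degenerate (coplanar) cloud
  gives 0 with a logged note.  Two normalizations are reported: per second of
  active console time (cm³/s) and per cm of summed path length (cm²).
* **Console sensitivity** is the tip/wrist path-length ratio per hand — a
  motion-scaling diagnostic, flagged when deviating more than 15 % (default)
  from the cohort median.

Undefined metrics (zero denominators, no samples) propagate as explicit
missing values — never 0 or ±inf — and are dropped per case downstream.

## Statistical comparison

The unit of analysis is the case: one value per case per cohort per
(step, metric), averaging within a case if several same-cohort operators
contributed.  Each cell is gated on normality: Shapiro–Wilk at α = 0.05 in
*both* groups (zero-variance groups count as non-normal; fewer than 3 values
per group skips the cell with a logged reason).  The parametric path is
Student's equal-variance independent *t* test (Welch available by flag) with
mean and 95 % *t*-CI (n−1 df) summaries; the nonparametric path is the
two-sided Mann–Whitney *U*, exact when both n ≤ 8 without ties, otherwise the
normal approximation with continuity and tie correction, with median [IQR]
summaries.  *p* < 0.05 is flagged.  Raw per-cell p-values are the primary
output across the many step × metric cells; a Benjamini–Hochberg mode exists
but is off by default.  All-identical inputs yield p = 1 by convention,
flagged degenerate.

## Synthetic case generator

The generator fabricates complete bundles with programmed ground truth; it
targets the sufficient statistics of the OPIs, not biomechanical realism.

* **Durations** are lognormal around a per-step median.
* **Activity** is an alternating exponential active/idle bout process with
  mean active bout 8 s, drawn once per (case, step) at the console level —
  the clutch engages and disengages both masters together — with each hand
  active during the leading fraction of every console bout so per-hand duty
  cycles nest inside the console duty cycle.  (Independent per-hand bout
  processes would make the dominant/non-dominant active-time ratio — hence
  dexterity — fluctuate with variance unrelated to any programmed parameter,
  and are physically wrong for a master console.)
* **Motion** is a two-timescale mean-reverting process: a slow workspace
  excursion (piecewise-linear interpolation of Gaussian knots every 3 s of
  active time, sd = `workspace_sigma_cm`) plus a fast Ornstein–Uhlenbeck
  detail component (1 s reversion time).  The fast amplitude is solved and
  the whole active-phase track then rescaled about its centroid so realized
  active path length / active time equals the hand's target speed exactly.  A
  single mean-reverting process cannot carry independent spread and speed at
  a fixed sample rate — after an exact speed rescale its spread is fully
  determined by the speed — hence the two timescales.  The tip freezes during
  idle bouts; the wrist stream is the tip shrunk by 1/motion-scale about its
  centroid, so the sensitivity ratio is exact by construction.
* **Between-case variability** (the case-level null model): multiplicative
  unit-mean lognormal jitter on speeds (cv 0.08), dominance (cv 0.15) and
  workspace sigma (cv 0.10), and one shared logit-normal shift (sd 0.3) on
  both hands' duty cycles per (case, step).
* **Seeding**: every stream's generator derives from (master seed, cohort,
  case, step, hand, purpose) via `SeedSequence`, so a fixed seed reproduces
  byte-identical bundles and adding cases never perturbs existing ones.

The **study preset** encodes six programmed effect *directions* between an
attending cohort (2 operators) and a trainee cohort (4 residents, 2 fellows):
higher attending dissection dominance (1.4 vs 0.75) and non-dominant speed
(3.74 vs 3.25 cm/s); lower attending pouch-creation non-dominant speed (3.91
vs 4.52 cm/s) with higher duty cycle (0.55 vs 0.33); higher attending
hand-sewn-anastomosis duty cycle (0.48 vs 0.23) with smaller workspace spread
(1.5 vs 2.2 cm).  The five remaining steps have identical cohort profiles and
serve as a built-in null.  The preset's problem size — 120 s median step
durations sampled at 25 Hz, 20 cases per cohort — is a desk-scale analog of a
clinical series, chosen so the activity-bout variance (which scales as
1/duration) does not swamp the programmed effects while a 100-replicate study
runs in minutes.

## What the validation shows — and does not

* Geometry is checked against independent oracles: path length vs brute-force
  pairwise summation (≤ 1e-9); hull volume vs a 10⁶-draw Delaunay-based
  point-in-hull Monte-Carlo estimate (≤ 1 %); the unit cube exactly.
* Metric identities hold to numerical precision: speed × active time = path
  length; hand-swap maps dexterity to its reciprocal; rigid transforms change
  no OPI beyond 1e-9 relative; scaling coordinates by k scales volumes by k³.
* Under the null (identical cohort distributions, 15 + 15 cases) the gated
  comparison rejects at 3.6–6.4 % over 1000 replicates for each metric
  family; calibration draws case-level values from the generator's own
  between-case distributions, which is exactly the input the inference layer
  sees (the kinematic layer itself is exercised by the replicate study).
* On the preset study (20 + 20 cases), all six programmed step × metric
  effects are recovered with the correct sign in ≈ 98 % of 100 replicates;
  null-step false-positive rates stay at the α level per metric; and the two
  workspace normalizations agree on the hand-sewn-anastomosis decision in
  ≈ 100 % of replicates.
* Generator parameters are inverted by the pipeline at 600 s step duration
  (averaged over 16 seeds): speeds and motion scale to float precision (the
  generator hits them by construction, so this checks bookkeeping, not
  estimation), dominance via the measured speed ratio, duty cycles within
  ~2 percentage points (residual bout-sampling noise).

Passing these checks shows the pipeline measures what the generator encodes
and that the inference layer is calibrated on the generator's case-level
distributions.  It does not show that clinical recordings share those
distributions: real tool motion is nonstationary and task-structured, real
activity detection has sensor noise, annotation boundaries are imperfect, and
surgeon effects cluster cases (the comparison treats cases as independent).
Findings on real data should be read with those caveats.

## Known limitations

* Convex-hull workspace overestimates occupied volume for non-convex motion;
  an alpha-shape alternative is a natural extension and the per-hand pooling
  choice is configurable in spirit (the hull routine accepts any point set).
* Camera-control, clutch-count, arm-swap and energy-event OPIs are out of
  scope, as are automatic step recognition and survey instruments.
* No mixed-effects modelling of surgeon-level clustering; cases are the
  replicates.
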