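# Methods

## Scope and model

`cedkit` analyzes studies that deliver a drug into brain tissue by
convection-enhanced delivery (CED) while co-infusing gadoteridol, a
gadolinium contrast agent, as a distribution surrogate. Four linked pieces
are implemented: subtraction-based MRI volumetry of the infusate
distribution volume (Vd), tumor-coverage metrics, Kaplan–Meier survival
endpoints, and a simulator of the accelerated-titration / 3+3
dose-escalation rules used by small phase-1 CED trials. A six-patient
clinical cohort (two tables: per-patient outcomes and per-infusion
volumetry) is bundled as CSV fixtures so the tabular analyses are fully
reproducible offline; the imaging chain is exercised on synthetic phantoms
because no trial imaging is publicly available.

## Subtraction volumetry

Gadolinium shortens T1, so tissue reached by the infusate brightens on
post-infusion T1-weighted MRI. The measurement model for the post scan is

    post = a · pre + b + Δ · 1{Vd} + ε,

where `(a, b)` is a global affine intensity drift between scanner sessions,
`Δ` the T1-shortening signal increase in perfused voxels, and `ε`
independent Gaussian noise. The chain is:

1. **Rigid co-registration** (post → pre) using a mean-squares metric,
   Euler angles + translation, regular-step gradient descent (SimpleITK).
   Same-session phantom pairs default to the identity.
2. **Reference-based normalization.** An anatomical structure the infusion
   cannot reach is segmented on the pre scan (seeded, intensity-windowed
   connected component). The post image is affinely mapped so its mean and
   standard deviation inside the reference match the pre image:
   `scale = sd_ref(pre)/sd_ref(post)`, `offset = mean_ref(pre) −
   scale·mean_ref(post)`. This two-parameter map exactly inverts any global
   affine drift and is invertible for testing; full histogram matching
   would add flexibility the model does not need. The residual standard
   deviation of `post_norm − pre` inside the reference estimates the
   session noise floor `σ`.
3. **Thresholding.** Vd = voxels in the region of interest with
   `post_norm − pre > k·σ` (default `k = 3`), after removing connected
   components smaller than `min_component_cm3` (default 0.05 cm³, a
   noise-speckle floor) and filling interior holes. When `σ = 0`
   (noise-free input) the threshold degenerates to strict positivity,
   floored at `1e-9 ×` the image intensity scale so floating-point
   cancellation dust is not segmented; this is logged.

Mean/SD matching has one caveat worth stating: scanner noise inflates
`sd_ref(post)` by `sqrt(1 + (σ_noise / (a·sd_ref_contrast))²)`, biasing the
scale low. The method therefore assumes the reference structure's internal
tissue contrast is well above the noise floor — true of usable anatomical
references, and built into the phantom (reference contrast ±40 intensity
units against noise σ = 5).

Volumes are `voxel count × voxel volume / 1000` cm³ at full precision;
rounding (half away from zero, 1 decimal) is presentation-only. Masks are
resampled between lattices with nearest-neighbor interpolation, images
trilinearly.

## Phantoms

`generate_phantom` builds the statistical structure the analysis assumes,
not convection physics (a convection–diffusion PDE is a non-goal):

- tumor: ellipsoid, FLAIR-hyperintense (200 vs background 100), default
  semi-axes (24, 18, 16) mm giving ≈ 29 cm³, the cohort's mean baseline
  tumor volume;
- infusate ground truth: ellipsoid with default volume ≈ 6.2 cm³ (the
  cohort's mean per-infusion Vd) minus a planar cap of `blocked_fraction`
  (default 0.15) of its volume, mimicking intratumoral regions that block
  delivery. The cap is cut at the normalized height `h` solving
  `(1−h)²(2+h)/4 = blocked_fraction`, so the carved volume has the closed
  form `(1 − blocked_fraction)·(4/3)πabc` — the analytic oracle for
  volume-conservation tests. A planar cut keeps the region convex, so hole
  filling cannot silently repair it;
- reference structure: ellipsoid disjoint from the infusate, intensity
  150 ± 40 along an internal radial gradient (nonzero variance even
  noise-free);
- corruption defaults: drift `a = 1.05`, `b = 10`; `Δ = 50`, `σ = 5`
  (signal-to-noise 10, the regime the recovery tests characterize).

What phantoms do **not** emulate: partial-volume effects, bias fields,
motion, deformable anatomy, T1 nonlinearity of contrast concentration, and
backflow along catheter tracts. Passing recovery tests therefore
demonstrate correctness of the measurement chain under its own model, not
clinical segmentation accuracy.

Synthetic cohorts draw survival times exponential with a configurable
median (default 14 months), loss to follow-up Bernoulli (default 1/6), and
per-cycle toxicity Bernoulli per dose level; infusion durations are normal
(361.6, 65) minutes truncated at zero, the cohort's observed distribution.
The infusion-rate ramp is a configurable table of (duration, rate)
segments because the clinical ramp description does not pin down a unique
schedule; nothing downstream depends on it.

## Coverage metrics

Per patient, total Vd is the union of per-treatment Vd masks on the
baseline lattice (never the sum — overlap is not double counted), coverage
is `100 × |Vd ∪ ∩ tumor| / |tumor|`, and convection efficiency is
`Vd/Vi`. The cohort Vd/Vi statistic is computed over each patient's
**first** infusion by default (one value per patient): first infusions are
the cleanest read of convection efficiency since repeat infusions partly
re-perfuse covered tissue, and this basis is the one under which the
bundled table reproduces its published cohort mean (2.6 ± 0.8; pooling all
13 infusions gives 2.2). The basis is a config enum (`first_infusion`,
`all_infusions`, `per_patient_total`).

Summary blocks report the sample (n−1) standard deviation as `sd` and the
population (n) form as `sd_pop`, because published small-cohort tables are
not always consistent about the convention; means are the primary
quantities. When only scalar volumes are supplied (table-based path), the
per-patient totals are taken as measured rather than recomputed.

## Survival

Overall survival runs from radiographic diagnosis to death; patients
without a recorded death contribute time to their off-study date. The one
lost-to-follow-up patient is handled under two policies: `lost_as_event`
(conservative: the loss counts as an event at its time) and
`lost_censored`. The product-limit estimator is implemented directly, with
deaths preceding censorings at tied times. Confidence intervals are
log-transformed Greenwood, `exp(log S ± 1.96·se(log S))` with
`se²(log S) = Σ d_i/(n_i(n_i−d_i))`, truncated to [0, 1] — the
`conf.type = "log"` convention of the R `survival` package, which is the
convention that reproduces the cohort's published intervals (plain
Greenwood does not; lifelines' default log(−log) interval also does not,
which is why lifelines serves as the independent cross-check of the curve
rather than the implementation). Median OS is the smallest event time with
`S(t) ≤ 0.5`. The median's lower confidence bound is not reported: no
standard construction reproduces a defensible value at n = 6.

## Dose escalation

The state machine implements an accelerated titration design (ATD):
single-patient cohorts escalate one level on grade 0–1 toxicity, hold on
tolerable grade 2, and de-escalate the individual patient on a
dose-limiting toxicity (DLT: intolerable grade 2 or related grade ≥ 3
neurological toxicity, or related systemic grade ≥ 3 excluding medically
managed nausea/vomiting/diarrhea, within 14 days of the last infusion).
Two cycle-1 triggers convert the design to a standard 3+3 at the current
level: the first cycle-1 DLT, or the second grade ≥ 2 occurrence across
the cohort's first cycles. Because one cycle can contribute several
grade ≥ 2 events, `CycleOutcome` carries an occurrence count
(`n_grade2plus_events`) alongside the maximum related grade. The
triggering patient counts toward the first 3+3 triplet (so two further
patients complete it), and any ATD patient already treated at that level
counts as a DLT-evaluable cohort member. In the 3+3 phase: 0/3 DLTs
escalate, 1/3 expands to six, 1/6 escalates, ≥ 2 DLTs at a level declare
the next lower level the recommended phase-2 dose (RP2D) — or no RP2D if
the level is the floor; escalation past the top configured level declares
it the RP2D. Intra-patient dose changes never move the cohort's enrollment
level.

`simulate_trial` samples one decision-driving outcome per patient (all
cohort rules key on cycle 1) with per-level probabilities (p_DLT,
p_grade2), a DLT preempting the grade-2 draw.
`enumerate_rp2d_distribution` computes the exact RP2D distribution by
walking the same state machine symbolically over the three outcome
categories per patient, memoized on the decision-relevant state
projection; it is the independent oracle the Monte-Carlo frequencies are
checked against (within three binomial standard errors at 10⁴
replicates).

## Problem sizes and numerical choices

Tests use 32³ phantoms (1 mm isotropic) with a 20-phantom recovery battery
at SNR 10 — sizes chosen so the full suite characterizes the chain in
seconds while leaving the default 64³ generator untouched. Registration
tests verify the identity case, an exact 2-voxel shift (recovered within
0.1 mm), and a noisy sub-voxel shift (within 0.5 mm). Oracle comparisons
(product-limit, two-pass mean/variance) are held to 1e−12; mask-equality
claims are exact, not approximate. Ties, degenerate inputs (zero-variance
reference, empty ROI, all-censored cohorts, single-subject summaries) each
have a defined behavior tested explicitly.

## Known limitations

- The volumetry threshold rule (`k·σ` on a normalized difference) is a
  reconstruction of a method whose exact threshold was never published;
  `k = 3` is a conventional choice, disclosed in the per-infusion report.
- Table-based coverage takes published per-patient totals as given; small
  inconsistencies from pre-rounding in the source table are preserved
  rather than "corrected".
- The escalation simulator abstracts each patient to one cycle-1 outcome;
  multi-cycle intra-patient trajectories affect only that patient's dose,
  not cohort decisions.
- The hypothesis test of 12-month survival against a historical 40% rate
  is out of scope: the design powered it for 19 patients and the cohort
  stopped at six.
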