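"""Synthetic MRI phantoms and cohort tables for end-to-end pipeline testing.

No imaging from the trial this package models was deposited, so every
downstream stage is exercised on phantoms built here. A phantom case holds:

* a pre-infusion T1 volume with a pontine-tumor ellipsoid and a separate
  reference structure (an anatomical region the infusion never reaches,
  carrying a smooth internal intensity gradient so it has nonzero variance);
* a post-infusion T1 equal to ``drift_scale * pre + drift_offset`` (global
  scanner drift between sessions) plus ``delta_intensity`` inside the
  ground-truth infusate region plus i.i.d. Gaussian noise;
* a FLAIR volume with a hyperintense tumor for seeded segmentation;
* ground-truth masks for tumor, infusate distribution, and reference.

The infusate ground truth is an ellipsoid with an optional planar cap
carved away, mimicking tumor regions that block infusate delivery. The cap
is cut perpendicular to the first axis at the normalized height whose cap
volume fraction equals ``blocked_fraction``, so the carved volume has the
closed form ``(1 - blocked_fraction) * (4/3) pi a b c`` — the analytic
oracle used by the volume-conservation tests. A convection-diffusion
simulation of real infusate transport is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .escalation import CycleOutcome
from .survival import Status, SurvivalRecord
from .volumetry import BinaryMask, ImageVolume

BACKGROUND_T1 = 100.0
TUMOR_T1 = 95.0
REFERENCE_T1 = 150.0
# Radial intensity gradient inside the reference structure. The reference
# anchors the mean/SD intensity normalization, whose scale estimate is
# inflated by a factor sqrt(1 + (noise/contrast)^2); anatomical structures
# usable as references have internal tissue contrast well above the noise
# floor, so the phantom gives its reference a +/-40 intensity range.
REFERENCE_T1_RANGE = 40.0
BACKGROUND_FLAIR = 100.0
TUMOR_FLAIR = 200.0

#: Mean and SD of infusion duration (minutes) observed across the modeled
#: trial's 13 infusions; synthetic infusion records draw from this normal
#: truncated at zero.
INFUSION_DURATION_MEAN_MIN = 361.6
INFUSION_DURATION_SD_MIN = 65.0

#: Infusion-rate ramp as (duration_min, rate_uL_per_min) segments; the last
#: segment's rate holds until the target volume is reached. The protocol
#: ramp (start 1 uL/min, stepwise increase to 10 uL/min) is configurable
#: because its exact schedule is a clinical judgment call.
DEFAULT_RAMP_SCHEDULE = tuple((15.0, float(r)) for r in range(1, 10)) + ((None, 10.0),)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and corruption parameters of one synthetic case (mm units)."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_center_mm: tuple[float, float, float] = (32.0, 32.0, 32.0)
    tumor_radii_mm: tuple[float, float, float] = (24.0, 18.0, 16.0)
    infusate_center_mm: tuple[float, float, float] = (32.0, 32.0, 32.0)
    infusate_radii_mm: tuple[float, float, float] = (12.5, 11.5, 10.3)
    blocked_fraction: float = 0.15
    delta_intensity: float = 50.0
    drift_scale: float = 1.05
    drift_offset: float = 10.0
    noise_sigma: float = 5.0
    reference_center_mm: tuple[float, float, float] = (10.0, 52.0, 52.0)
    reference_radii_mm: tuple[float, float, float] = (6.0, 6.0, 6.0)

    def __post_init__(self) -> None:
        for name in ("tumor_radii_mm", "infusate_radii_mm", "reference_radii_mm"):
            if any(r <= 0 for r in getattr(self, name)):
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 <= self.blocked_fraction <= 1.0):
            raise ValueError("blocked_fraction must lie in [0, 1]")
        if self.delta_intensity < 0 or self.noise_sigma < 0:
            raise ValueError("delta_intensity and noise_sigma must be nonnegative")
        if self.drift_scale <= 0:
            raise ValueError("drift_scale must be positive")
        bounds = [
            (n - 1) * s for n, s in zip(self.grid_shape, self.spacing_mm)
        ]
        for name, center, radii in (
            ("tumor", self.tumor_center_mm, self.tumor_radii_mm),
            ("infusate", self.infusate_center_mm, self.infusate_radii_mm),
            ("reference", self.reference_center_mm, self.reference_radii_mm),
        ):
            for c, r, b in zip(center, radii, bounds):
                if c - r < 0 or c + r > b:
                    raise ValueError(
                        f"{name} ellipsoid (center {center} mm, radii {radii} mm) "
                        f"exceeds the grid"
                    )


@dataclass(frozen=True)
class PhantomCase:
    pre_t1: ImageVolume
    post_t1: ImageVolume
    flair: ImageVolume
    tumor_truth: BinaryMask
    vd_truth: BinaryMask
    reference_mask: BinaryMask
    spec: PhantomSpec
    seed: int


def _grid_mm(spec: PhantomSpec):
    axes = [
        np.arange(n) * s for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_field(grid, center, radii) -> np.ndarray:
    """Normalized squared radius: <= 1 inside the ellipsoid."""
    return sum(((g - c) / r) ** 2 for g, c, r in zip(grid, center, radii))


def cap_height_for_fraction(fraction: float) -> float:
    """Normalized plane height h such that the unit-ball cap above u = h has
    the given volume fraction: fraction = (1 - h)^2 (2 + h) / 4."""
    if fraction <= 0.0:
        return 1.0
    if fraction >= 1.0:
        return -1.0
    return brentq(lambda h: (1 - h) ** 2 * (2 + h) / 4 - fraction, -1.0, 1.0)


def carved_ellipsoid_volume_cm3(radii_mm, blocked_fraction: float) -> float:
    """Analytic volume of the infusate ground truth in cm^3."""
    full = 4.0 / 3.0 * np.pi * np.prod(radii_mm)
    return float(full * (1.0 - blocked_fraction)) / 1000.0


def generate_phantom(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Build one phantom case; identical (spec, seed) yields identical arrays."""
    rng = np.random.default_rng(seed)
    grid = _grid_mm(spec)

    tumor = _ellipsoid_field(grid, spec.tumor_center_mm, spec.tumor_radii_mm) <= 1.0
    inf_field = _ellipsoid_field(grid, spec.infusate_center_mm, spec.infusate_radii_mm)
    infusate_full = inf_field <= 1.0
    h = cap_height_for_fraction(spec.blocked_fraction)
    u = (grid[0] - spec.infusate_center_mm[0]) / spec.infusate_radii_mm[0]
    vd_truth = infusate_full & (u <= h)

    ref_field = _ellipsoid_field(grid, spec.reference_center_mm, spec.reference_radii_mm)
    reference = ref_field <= 1.0
    if (reference & infusate_full).any():
        raise ValueError("reference structure overlaps the infusate ellipsoid")

    pre = np.full(spec.grid_shape, BACKGROUND_T1)
    pre[tumor] = TUMOR_T1
    # smooth radial gradient keeps the reference's intensity variance nonzero
    pre[reference] = REFERENCE_T1 + REFERENCE_T1_RANGE * (
        2.0 * np.sqrt(ref_field[reference]) - 1.0
    )

    post = spec.drift_scale * pre + spec.drift_offset
    post[vd_truth] += spec.delta_intensity
    if spec.noise_sigma > 0:
        post = post + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)

    flair = np.full(spec.grid_shape, BACKGROUND_FLAIR)
    flair[tumor] = TUMOR_FLAIR

    sp, orig = spec.spacing_mm, (0.0, 0.0, 0.0)
    return PhantomCase(
        pre_t1=ImageVolume(pre, sp, orig),
        post_t1=ImageVolume(post, sp, orig),
        flair=ImageVolume(flair, sp, orig),
        tumor_truth=BinaryMask(tumor, sp, orig),
        vd_truth=BinaryMask(vd_truth, sp, orig),
        reference_mask=BinaryMask(reference, sp, orig),
        spec=spec,
        seed=int(seed),
    )


# --- synthetic cohorts ------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters of a synthetic trial cohort.

    Defaults mirror the modeled study conditions: a six-patient cohort,
    exponential survival with 14-month median, one-in-six loss to
    follow-up, and up to five treatment cycles per patient.
    """

    n_patients: int = 6
    dlt_prob_per_dose: tuple[float, ...] = (0.1, 0.2)
    grade2_prob_per_dose: tuple[float, ...] = (0.2, 0.3)
    survival_median_months: float = 14.0
    lost_prob: float = 1.0 / 6.0
    max_cycles: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if len(self.dlt_prob_per_dose) != len(self.grade2_prob_per_dose):
            raise ValueError("probability vectors must cover the same dose levels")
        for v in (*self.dlt_prob_per_dose, *self.grade2_prob_per_dose, self.lost_prob):
            if not (0.0 <= v <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.survival_median_months <= 0 or self.max_cycles < 1:
            raise ValueError("median survival and max_cycles must be positive")


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[SurvivalRecord], list[CycleOutcome]]:
    """Draw a synthetic cohort: survival records and per-cycle toxicity.

    Survival times are exponential with the configured median (rate
    ln 2 / median); lost-to-follow-up status is Bernoulli(lost_prob), else
    death. Each patient receives a uniform 1..max_cycles cycles at a dose
    level drawn uniformly from the configured ladder, with per-cycle DLT and
    tolerable-grade-2 outcomes Bernoulli at that level's probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    n_levels = len(spec.dlt_prob_per_dose)
    survival: list[SurvivalRecord] = []
    toxicity: list[CycleOutcome] = []
    for i in range(spec.n_patients):
        sid = f"SYN-{i + 1}"
        time = rng.exponential(spec.survival_median_months / np.log(2.0))
        status = Status.LOST if rng.random() < spec.lost_prob else Status.DEATH
        survival.append(SurvivalRecord(sid, max(float(time), 1e-6), status))
        dl = int(rng.integers(1, n_levels + 1))
        n_cycles = int(rng.integers(1, spec.max_cycles + 1))
        for cycle in range(1, n_cycles + 1):
            is_dlt = rng.random() < spec.dlt_prob_per_dose[dl - 1]
            grade2 = (not is_dlt) and rng.random() < spec.grade2_prob_per_dose[dl - 1]
            grade = 3 if is_dlt else (2 if grade2 else 0)
            toxicity.append(
                CycleOutcome(sid, cycle, dl, max_related_grade=grade,
                             tolerable_grade2=not is_dlt)
            )
    return survival, toxicity


@dataclass(frozen=True)
class SyntheticInfusion:
    subject_id: str
    ced_number: int
    infusion_volume_mL: float
    duration_min: float


def ramp_duration_min(vi_mL: float, schedule=DEFAULT_RAMP_SCHEDULE) -> float:
    """Nominal infusion duration for a target volume under a ramp schedule."""
    remaining_uL = vi_mL * 1000.0
    total = 0.0
    for duration, rate in schedule:
        if duration is None:
            return total + remaining_uL / rate
        delivered = duration * rate
        if delivered >= remaining_uL:
            return total + remaining_uL / rate
        remaining_uL -= delivered
        total += duration
    raise ValueError("ramp schedule exhausted before reaching the target volume")


def generate_infusions(
    n: int, vi_mL: float = 3.0, seed: int = 0
) -> list[SyntheticInfusion]:
    """Synthetic infusion records with durations ~ Normal(361.6, 65) truncated at 0."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        d = -1.0
        while d <= 0:
            d = rng.normal(INFUSION_DURATION_MEAN_MIN, INFUSION_DURATION_SD_MIN)
        out.append(SyntheticInfusion(f"SYN-{i + 1}", 1, vi_mL, float(d)))
    return out


def cohort_to_frame(records: list[SurvivalRecord]) -> pd.DataFrame:
    """Survival records as a cohort-table DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "subject": [r.subject_id for r in records],
            "followup_months": [r.time_months for r in records],
            "status": [r.status.value for r in records],
        }
    )
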