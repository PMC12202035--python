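"""Per-infusion and per-patient infusate distribution and tumor-coverage metrics.

Each convection-enhanced delivery (CED) treatment produces a gadoteridol
distribution volume Vd (cm^3) segmented from the post-infusion T1 signal
change. Per patient, the union of all treatment Vd masks intersected with
the baseline FLAIR tumor mask gives the covered tumor volume; coverage is
that volume as a percentage of the tumor volume. Convection efficiency is
summarized by the ratio Vd/Vi, distribution volume per unit infused volume
(cm^3 and mL coincide).

Inputs may be mask-based (BinaryMask objects per infusion) or table-based
(scalar volumes already measured, as shipped in the bundled clinical
fixture). Both paths populate the same PatientCoverage records.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .volumetry import BinaryMask, ImageVolume, mask_volume_cm3, resample_mask


class VdViBasis(str, enum.Enum):
    """Which infusions enter the cohort Vd/Vi summary.

    ``first_infusion`` (one ratio per patient, from CED #1) is the default:
    first infusions are the cleanest read of convection efficiency because
    later infusions partially overlap already-perfused tissue.
    """

    FIRST_INFUSION = "first_infusion"
    ALL_INFUSIONS = "all_infusions"
    PER_PATIENT_TOTAL = "per_patient_total"


@dataclass(frozen=True)
class InfusionRecord:
    """One CED treatment for one subject."""

    subject_id: str
    ced_number: int
    gad_concentration_mM: float
    infusion_volume_mL: float
    duration_min: float
    vd_cm3: float
    vd_mask: BinaryMask | None = None

    def __post_init__(self) -> None:
        if self.ced_number < 1:
            raise ValueError("ced_number must be a positive integer")
        if self.infusion_volume_mL <= 0:
            raise ValueError("infusion volume Vi must be positive")
        if self.vd_cm3 < 0:
            raise ValueError("vd_cm3 must be nonnegative")


@dataclass(frozen=True)
class PatientCoverage:
    subject_id: str
    tumor_volume_cm3: float
    total_vd_cm3: float
    tumor_covered_cm3: float
    coverage_percent: float
    outside_tumor_cm3: float

    def __post_init__(self) -> None:
        eps = 1e-9
        if self.tumor_covered_cm3 > self.total_vd_cm3 + eps:
            raise ValueError(
                f"{self.subject_id}: covered volume exceeds total distribution volume"
            )
        if self.tumor_covered_cm3 > self.tumor_volume_cm3 + eps:
            raise ValueError(f"{self.subject_id}: covered volume exceeds tumor volume")
        if self.outside_tumor_cm3 < -eps:
            raise ValueError(f"{self.subject_id}: negative outside-tumor volume")


def union_vd(masks: Sequence[BinaryMask], reference_lattice: ImageVolume) -> BinaryMask:
    """Voxel-wise OR of per-treatment Vd masks on the baseline lattice.

    Masks from different sessions are nearest-neighbor resampled onto the
    reference lattice first, so overlapping distributions are never double
    counted.
    """
    if len(masks) == 0:
        raise ValueError("union_vd requires at least one mask")
    out = np.zeros(reference_lattice.shape, dtype=bool)
    for m in masks:
        out |= resample_mask(m, reference_lattice).voxels
    return BinaryMask(out, reference_lattice.spacing_mm, reference_lattice.origin_mm)


def coverage_percent(tumor_covered_cm3: float, tumor_volume_cm3: float) -> float:
    """Covered tumor volume as a percentage of the lesion volume."""
    if tumor_volume_cm3 <= 0:
        raise ValueError("tumor volume must be positive")
    if tumor_covered_cm3 < 0 or tumor_covered_cm3 > tumor_volume_cm3 + 1e-9:
        raise ValueError("covered volume must lie in [0, tumor volume]")
    return 100.0 * tumor_covered_cm3 / tumor_volume_cm3


def vd_vi_ratio(vd_cm3: float, vi_mL: float) -> float:
    """Convection efficiency Vd/Vi (dimensionless; cm^3 and mL are the same unit)."""
    if vi_mL <= 0:
        raise ValueError("infusion volume Vi must be positive")
    if vd_cm3 < 0:
        raise ValueError("Vd must be nonnegative")
    return vd_cm3 / vi_mL


def cohort_summary(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cohort_summary requires a nonempty list")
    if vals.size < 2:
        raise ValueError("sample standard deviation needs at least two values")
    return float(vals.mean()), float(vals.std(ddof=1))


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Presentation rounding: half away from zero (what clinical tables print)."""
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def read_infusion_table(path_or_df) -> pd.DataFrame:
    """Load a per-infusion clinical table CSV.

    Expected columns: subject, ced_number, gad_mM, vi_mL, duration_min,
    tumor_cm3, vd_cm3, total_vd_cm3, covered_cm3, coverage_pct. Per-patient
    columns (tumor, total, covered, coverage) are populated on the first
    infusion row only and may be blank elsewhere.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = {"subject", "ced_number", "vi_mL", "duration_min", "vd_cm3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"infusion table missing columns: {sorted(missing)}")
    return df


def records_from_table(df: pd.DataFrame) -> list[InfusionRecord]:
    return [
        InfusionRecord(
            subject_id=str(r.subject),
            ced_number=int(r.ced_number),
            gad_concentration_mM=float(getattr(r, "gad_mM", float("nan"))),
            infusion_volume_mL=float(r.vi_mL),
            duration_min=float(r.duration_min),
            vd_cm3=float(r.vd_cm3),
        )
        for r in df.itertuples()
    ]


def _patient_rows_from_masks(
    records: Sequence[InfusionRecord],
    tumor_masks: Mapping[str, BinaryMask],
    baselines: Mapping[str, ImageVolume],
) -> list[PatientCoverage]:
    rows = []
    for sid in sorted({r.subject_id for r in records}):
        recs = [r for r in records if r.subject_id == sid]
        if any(r.vd_mask is None for r in recs):
            raise ValueError(f"subject {sid}: mask-based path needs a vd_mask per infusion")
        lattice = baselines[sid]
        union = union_vd([r.vd_mask for r in recs], lattice)
        tumor = resample_mask(tumor_masks[sid], lattice)
        total = mask_volume_cm3(union)
        covered_mask = BinaryMask(
            union.voxels & tumor.voxels, lattice.spacing_mm, lattice.origin_mm
        )
        covered = mask_volume_cm3(covered_mask)
        tumor_vol = mask_volume_cm3(tumor)
        rows.append(
            PatientCoverage(
                subject_id=sid,
                tumor_volume_cm3=tumor_vol,
                total_vd_cm3=total,
                tumor_covered_cm3=covered,
                coverage_percent=coverage_percent(covered, tumor_vol),
                outside_tumor_cm3=total - covered,
            )
        )
    return rows


def _patient_rows_from_table(df: pd.DataFrame) -> list[PatientCoverage]:
    rows = []
    for sid, grp in df.groupby("subject", sort=True):
        first = grp[grp["ced_number"] == 1]
        if first.empty or pd.isna(first["tumor_cm3"].iloc[0]):
            raise ValueError(f"subject {sid}: no baseline tumor volume in table")
        tumor_vol = float(first["tumor_cm3"].iloc[0])
        total = float(first["total_vd_cm3"].iloc[0])
        covered = float(first["covered_cm3"].iloc[0])
        pct = first["coverage_pct"].iloc[0]
        pct = coverage_percent(covered, tumor_vol) if pd.isna(pct) else float(pct)
        rows.append(
            PatientCoverage(
                subject_id=str(sid),
                tumor_volume_cm3=tumor_vol,
                total_vd_cm3=total,
                tumor_covered_cm3=covered,
                coverage_percent=pct,
                outside_tumor_cm3=total - covered,
            )
        )
    return rows


def build_coverage_table(
    records: Sequence[InfusionRecord],
    *,
    table: pd.DataFrame | None = None,
    tumor_masks: Mapping[str, BinaryMask] | None = None,
    baselines: Mapping[str, ImageVolume] | None = None,
    vd_vi_basis: VdViBasis | str = VdViBasis.FIRST_INFUSION,
) -> tuple[list[PatientCoverage], dict]:
    """Assemble per-patient coverage rows and the cohort summary block.

    Scalar-table inputs (``table``) take per-patient totals as measured;
    mask inputs recompute them from the voxel grids. The summary block
    reports mean and both standard-deviation conventions (sample ``sd`` and
    population ``sd_pop``) for: baseline tumor volume, per-infusion Vd,
    coverage %, Vd/Vi on the configured basis, outside-tumor volume, and
    infusion duration.
    """
    basis = VdViBasis(vd_vi_basis)
    if tumor_masks is not None:
        if baselines is None:
            raise ValueError("mask-based path requires baseline lattices")
        patients = _patient_rows_from_masks(records, tumor_masks, baselines)
    elif table is not None:
        patients = _patient_rows_from_table(table)
    else:
        raise ValueError("provide either tumor_masks+baselines or a scalar table")

    by_subject: dict[str, list[InfusionRecord]] = {}
    for r in sorted(records, key=lambda r: (r.subject_id, r.ced_number)):
        by_subject.setdefault(r.subject_id, []).append(r)
    for sid in {p.subject_id for p in patients}:
        if sid not in by_subject:
            raise ValueError(f"subject {sid}: no infusion records")

    if basis is VdViBasis.FIRST_INFUSION:
        ratios = [
            vd_vi_ratio(rs[0].vd_cm3, rs[0].infusion_volume_mL)
            for rs in by_subject.values()
        ]
    elif basis is VdViBasis.ALL_INFUSIONS:
        ratios = [vd_vi_ratio(r.vd_cm3, r.infusion_volume_mL) for r in records]
    else:  # per-patient total Vd over total Vi
        ratios = [
            vd_vi_ratio(p.total_vd_cm3, sum(r.infusion_volume_mL for r in by_subject[p.subject_id]))
            for p in patients
        ]

    def block(values: Sequence[float]) -> dict:
        arr = np.asarray(values, dtype=float)
        if arr.size >= 2:
            mean, sd = cohort_summary(values)
        else:  # a single subject has no dispersion estimate
            mean, sd = float(arr[0]), float("nan")
        return {"mean": mean, "sd": sd, "sd_pop": float(arr.std(ddof=0)), "n": len(values)}

    summary = {
        "n_patients": len(patients),
        "n_infusions": len(records),
        "tumor_volume_cm3": block([p.tumor_volume_cm3 for p in patients]),
        "vd_per_infusion_cm3": block([r.vd_cm3 for r in records]),
        "coverage_percent": block([p.coverage_percent for p in patients]),
        "vd_vi_ratio": {**block(ratios), "basis": basis.value},
        "outside_tumor_cm3": block([p.outside_tumor_cm3 for p in patients]),
        "infusion_duration_min": block([r.duration_min for r in records]),
        "coverage_max_percent": max(p.coverage_percent for p in patients),
    }
    return patients, summary
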