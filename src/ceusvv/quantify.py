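"""Maximal video-intensity enhancement (MVE) and normalized MVE.

MVE is the headline CEUS statistic: the peak of an ROI's time–intensity
curve minus the background video-intensity measured before contrast
arrival.  The adventitial MVE is normalized by the MVE of a luminal
reference ROI drawn proximal to the lesion, giving a dimensionless proxy
for vasa-vasorum density that is robust to per-acquisition gain.

By default both numerator and denominator are background-subtracted MVEs;
normalizing raw TIC maxima instead (which leaves the ratio dependent on
tissue baseline) is available as a sensitivity variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    DegenerateReferenceError,
    IntegrityError,
    InvalidParameterError,
)
from .imaging import TimeIntensityCurve

__all__ = [
    "MveResult",
    "NormalizedMve",
    "AnimalRecord",
    "compute_mve",
    "normalized_mve",
    "build_cohort_table",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

#: group whose lumen is occluded by plaque; imaged for direct observation
#: only, so no normalized MVE can be computed for it
OCCLUSIVE_GROUP = 5

COHORT_COLUMNS = ["animal_id", "group_id", "nmve", "cd31_mean", "vegf_mean"]


@dataclass(frozen=True)
class MveResult:
    """Background-subtracted peak enhancement of one ROI."""

    roi_label: str
    peak_intensity: float
    background_intensity: float
    mve: float
    peak_time: float
    warning: str | None = None


@dataclass(frozen=True)
class NormalizedMve:
    """Adventitia-to-lumen enhancement ratio (dimensionless)."""

    value: float
    adventitia_mve: float
    lumen_mve: float
    variant: str = "subtracted"


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's quantified imaging and histology read-outs.

    ``nmve`` is None for the occlusive-plaque group, whose luminal reference
    cannot be enhanced; histology counts are observer means and must be
    non-negative.
    """

    animal_id: str
    group_id: int
    nmve: float | None
    cd31_mean: float
    vegf_mean: float


def compute_mve(tic: TimeIntensityCurve, background: float) -> MveResult:
    """Peak TIC intensity minus ``background``.

    The peak is the maximum of the (possibly smoothed) curve; ties are broken
    by the earliest frame.  A negative MVE (background above every frame, a
    noise artefact) is reported with a warning rather than clamped, so the
    statistic's sampling distribution is not truncated.
    """
    if len(tic) == 0:
        raise InvalidParameterError("TIC is empty")
    if not np.isfinite(background):
        raise InvalidParameterError("background must be finite")
    idx = int(np.argmax(tic.intensities))  # argmax returns the first maximum
    peak = float(tic.intensities[idx])
    mve = peak - float(background)
    return MveResult(
        roi_label=tic.roi_label,
        peak_intensity=peak,
        background_intensity=float(background),
        mve=mve,
        peak_time=float(tic.times[idx]),
        warning="negative MVE: background exceeds peak" if mve < 0 else None,
    )


def normalized_mve(
    adventitia: MveResult,
    lumen: MveResult,
    variant: str = "subtracted",
) -> NormalizedMve:
    """Adventitial enhancement divided by luminal enhancement.

    ``variant="subtracted"`` (default) forms the ratio of background-
    subtracted MVEs; ``variant="raw-max"`` divides raw peak intensities, a
    sensitivity analysis that retains the tissue baseline in both terms.
    A non-positive luminal reference signals failed luminal enhancement and
    raises :class:`DegenerateReferenceError`.
    """
    if variant == "subtracted":
        num, den = adventitia.mve, lumen.mve
    elif variant == "raw-max":
        num, den = adventitia.peak_intensity, lumen.peak_intensity
    else:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    if den <= 0:
        raise DegenerateReferenceError(
            f"luminal reference enhancement is {den:g} <= 0"
        )
    return NormalizedMve(
        value=num / den,
        adventitia_mve=adventitia.mve,
        lumen_mve=lumen.mve,
        variant=variant,
    )


def build_cohort_table(records: Iterable[AnimalRecord]) -> pd.DataFrame:
    """Assemble per-animal records into a validated cohort table.

    One row per animal with columns ``animal_id, group_id, nmve, cd31_mean,
    vegf_mean``; the occlusive group's ``nmve`` is left missing.  Integrity
    violations (duplicate ids, negative counts, an nmve recorded for the
    occlusive group) raise :class:`IntegrityError`.
    """
    records = list(records)
    if not records:
        raise IntegrityError("no records")
    rows = []
    for r in records:
        if r.group_id < 0:
            raise IntegrityError(f"{r.animal_id}: negative group_id")
        if r.cd31_mean < 0 or r.vegf_mean < 0:
            raise IntegrityError(f"{r.animal_id}: negative histology count")
        if r.group_id == OCCLUSIVE_GROUP and r.nmve is not None:
            raise IntegrityError(
                f"{r.animal_id}: normalized MVE recorded for the "
                "occlusive-plaque group"
            )
        if r.nmve is None and r.group_id != OCCLUSIVE_GROUP:
            raise IntegrityError(f"{r.animal_id}: missing normalized MVE")
        rows.append(
            {
                "animal_id": r.animal_id,
                "group_id": int(r.group_id),
                "nmve": np.nan if r.nmve is None else float(r.nmve),
                "cd31_mean": float(r.cd31_mean),
                "vegf_mean": float(r.vegf_mean),
            }
        )
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if df["animal_id"].duplicated().any():
        dupes = df.loc[df["animal_id"].duplicated(), "animal_id"].tolist()
        raise IntegrityError(f"duplicate animal ids: {dupes}")
    return df


def validate_cohort(df: pd.DataFrame) -> dict:
    """Validate a cohort table and return a summary report.

    Raises :class:`IntegrityError` on any violation; otherwise reports row
    counts per group and how many rows lack a normalized MVE.
    """
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise IntegrityError(f"missing columns: {sorted(missing)}")
    if df["animal_id"].duplicated().any():
        raise IntegrityError("duplicate animal ids")
    if (df[["cd31_mean", "vegf_mean"]] < 0).any().any():
        raise IntegrityError("negative histology count")
    occl = df["group_id"] == OCCLUSIVE_GROUP
    if df.loc[occl, "nmve"].notna().any():
        raise IntegrityError("normalized MVE present for occlusive group")
    if df.loc[~occl, "nmve"].isna().any():
        raise IntegrityError("missing normalized MVE outside occlusive group")
    return {
        "n_animals": int(len(df)),
        "n_groups": int(df["group_id"].nunique()),
        "rows_per_group": df["group_id"].value_counts().sort_index().to_dict(),
        "n_missing_nmve": int(df["nmve"].isna().sum()),
    }


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (full float precision, round-trip exact)."""
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    # round_trip parsing keeps read(write(df)) exactly equal to df
    df = pd.read_csv(path, dtype={"animal_id": str}, float_precision="round_trip")
    validate_cohort(df)
    return df
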