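"""Spirometry reference values and measured-maneuver selection.

Predicted FVC and FEV1 (with lower limits of normal) come from the NHANES
III reference equations of Hankinson et al. (1999), which model lung
function as a quadratic in age plus a height-squared term, stratified by
sex and by three race/ethnicity groups. Measured spirometry enters the
pipeline through the standard best-maneuver rule: the acceptable maneuver
with the highest FVC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._nhanes import AGE_SPLIT, COEFFICIENTS, RACES

__all__ = [
    "RACES",
    "SubjectRecord",
    "SpirometryManeuver",
    "LungFunctionPrediction",
    "predict_lung_function",
    "select_best_maneuver",
    "percent_predicted",
    "read_subject_roster",
]

AGE_RANGE = (8.0, 80.0)
HEIGHT_RANGE = (100.0, 220.0)

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class SpirometryManeuver:
    """One forced expiratory maneuver: FVC and FEV1 in liters."""

    fvc: float
    fev1: float
    acceptable: bool = True

    def __post_init__(self):
        if not 0 < self.fev1 <= self.fvc:
            raise ValueError(
                f"maneuver requires 0 < FEV1 <= FVC, got FEV1={self.fev1}, FVC={self.fvc}"
            )


@dataclass
class SubjectRecord:
    """Demographics, anthropometry and measured spirometry for one participant.

    sex is coded 0 for male, 1 for female. height in cm, weight in kg,
    volumes in liters.
    """

    subject_id: str
    age: float
    sex: int
    height: float
    weight: float
    race: str
    fvc_measured: float
    fev1_measured: float
    bmi: float = field(default=None)  # type: ignore[assignment]
    fev1_fvc: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.height <= 0 or self.weight <= 0:
            raise ValueError("height and weight must be positive")
        if not 0 < self.fev1_measured <= self.fvc_measured:
            raise ValueError("requires 0 < FEV1 <= FVC")
        if self.sex not in (0, 1):
            raise ValueError("sex must be coded 0 (male) or 1 (female)")
        bmi = self.weight / (self.height / 100.0) ** 2
        if self.bmi is None:
            self.bmi = bmi
        elif abs(self.bmi - bmi) > 1e-6:
            raise ValueError(f"bmi {self.bmi} inconsistent with weight/height ({bmi:.4f})")
        ratio = self.fev1_measured / self.fvc_measured
        if self.fev1_fvc is None:
            self.fev1_fvc = ratio
        elif abs(self.fev1_fvc - ratio) > 1e-6:
            raise ValueError("fev1_fvc inconsistent with fev1/fvc")


@dataclass(frozen=True)
class LungFunctionPrediction:
    """NHANES III predicted volumes (L) and lower limits of normal."""

    fvc: ArrayLike
    fev1: ArrayLike
    fvc_lln: ArrayLike
    fev1_lln: ArrayLike


def _normalize_sex(sex) -> str:
    if isinstance(sex, str):
        s = sex.strip().lower()
        if s in ("m", "male", "0"):
            return "male"
        if s in ("f", "female", "1"):
            return "female"
        raise ValueError(f"unrecognized sex code {sex!r}")
    return "female" if int(sex) == 1 else "male"


def predict_lung_function(
    age: ArrayLike,
    height: ArrayLike,
    sex,
    race: str,
    race_map: Optional[Mapping[str, str]] = None,
) -> LungFunctionPrediction:
    """Predicted FVC/FEV1 and lower limits of normal, NHANES III equations.

    Parameters
    ----------
    age : years (decimal years as supplied; no rounding).
    height : cm.
    sex : 0/"M"/"male" or 1/"F"/"female".
    race : one of ``caucasian``, ``african_american``, ``mexican_american``,
        or a key of ``race_map`` translating other categories onto those
        three. Unknown categories are refused rather than guessed.
    """
    if race_map and race in race_map:
        race = race_map[race]
    if race not in RACES:
        raise ValueError(
            f"unknown race category {race!r}; supported categories are {', '.join(RACES)} "
            "(supply race_map to translate other categories)"
        )
    age = np.asarray(age, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(age < AGE_RANGE[0]) or np.any(age > AGE_RANGE[1]):
        raise ValueError(f"age out of supported range {AGE_RANGE}")
    if np.any(height < HEIGHT_RANGE[0]) or np.any(height > HEIGHT_RANGE[1]):
        raise ValueError(f"height out of supported range {HEIGHT_RANGE} cm")
    sex_name = _normalize_sex(sex)
    split = AGE_SPLIT[sex_name]

    def _evaluate(measure: str):
        youth = COEFFICIENTS[(sex_name, race, measure, "youth")]
        adult = COEFFICIENTS[(sex_name, race, measure, "adult")]
        out_pred = np.empty_like(age)
        out_lln = np.empty_like(age)
        is_youth = age < split
        for mask, (b0, b1, b2, b3, b3_lln) in ((is_youth, youth), (~is_youth, adult)):
            poly = b0 + b1 * age + b2 * age**2
            out_pred = np.where(mask, poly + b3 * height**2, out_pred)
            out_lln = np.where(mask, poly + b3_lln * height**2, out_lln)
        return out_pred, out_lln

    fvc, fvc_lln = _evaluate("fvc")
    fev1, fev1_lln = _evaluate("fev1")
    if age.ndim == 0:
        fvc, fev1, fvc_lln, fev1_lln = (float(v) for v in (fvc, fev1, fvc_lln, fev1_lln))
    return LungFunctionPrediction(fvc=fvc, fev1=fev1, fvc_lln=fvc_lln, fev1_lln=fev1_lln)


def select_best_maneuver(maneuvers: Sequence[SpirometryManeuver]) -> SpirometryManeuver:
    """The acceptable maneuver with the highest FVC."""
    maneuvers = list(maneuvers)
    if not maneuvers:
        raise ValueError("no maneuvers supplied")
    acceptable = [m for m in maneuvers if m.acceptable]
    if not acceptable:
        raise ValueError("no acceptable maneuver among the supplied set")
    return max(acceptable, key=lambda m: m.fvc)


def percent_predicted(measured: ArrayLike, predicted: ArrayLike) -> ArrayLike:
    """Measured lung function as a percentage of the reference prediction."""
    predicted = np.asarray(predicted, dtype=float)
    if np.any(predicted <= 0):
        raise ValueError("predicted value must be positive")
    out = 100.0 * np.asarray(measured, dtype=float) / predicted
    return float(out) if out.ndim == 0 else out


def read_subject_roster(path) -> pd.DataFrame:
    """Read a subject roster CSV.

    Expected header: subject_id, age, sex, height_cm, weight_kg, race,
    fvc_L, fev1_L. Sex is accepted as 0/1 or M/F and normalized to 0/1.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "age", "sex", "height_cm", "weight_kg", "race", "fvc_L", "fev1_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"roster is missing columns: {sorted(missing)}")
    df = df.copy()
    df["sex"] = [1 if _normalize_sex(s) == "female" else 0 for s in df["sex"]]
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def subjects_from_roster(df: pd.DataFrame) -> list[SubjectRecord]:
    """Materialize SubjectRecord objects from a roster dataframe."""
    return [
        SubjectRecord(
            subject_id=str(r.subject_id),
            age=float(r.age),
            sex=int(r.sex),
            height=float(r.height_cm),
            weight=float(r.weight_kg),
            race=str(r.race),
            fvc_measured=float(r.fvc_L),
            fev1_measured=float(r.fev1_L),
        )
        for r in df.itertuples(index=False)
    ]
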