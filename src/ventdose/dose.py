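"""Ventilation prediction in the field and inhaled-dose integration.

A fitted ventilation model (V̇E/FVC as a linear function of HR and
optionally f_B) is evaluated against a field heart-rate record, rescaled
by the subject's FVC (measured, or NHANES-III-predicted in its absence),
and integrated against a time-resolved pollutant concentration series:

    exposure  = ∫ C dt              [µg·min·m⁻³]
    volume    = ∫ V̇E dt / 1000     [m³]
    dose      = ∫ C·V̇E dt / 1000   [µg]

by the rectangle rule on the concentration's native 1-minute grid; the
per-minute ventilation is the mean of per-second predictions within that
minute, and partial leading/trailing minutes are weighted by coverage.
Negative predicted ventilation (possible when extrapolating the linear
model to very low HR) is floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .spirometry import predict_lung_function

__all__ = [
    "VentilationModel",
    "MODEL_1",
    "MODEL_2",
    "MODEL_FB_ONLY",
    "MODEL_2_NHANES",
    "predict_ve",
    "compute_dose",
    "rest_counterfactual",
]


@dataclass(frozen=True)
class VentilationModel:
    """Linear model for FVC-normalized minute ventilation (min⁻¹)."""

    intercept: float
    coef_hr: float = 0.0
    coef_fb: float = 0.0
    fvc_source: str = "measured"  # or "nhanes_predicted"
    name: str = "custom"

    def __post_init__(self):
        if self.coef_hr == 0.0 and self.coef_fb == 0.0:
            raise ValueError("at least one of coef_hr, coef_fb must be nonzero")
        if self.fvc_source not in ("measured", "nhanes_predicted"):
            raise ValueError("fvc_source must be 'measured' or 'nhanes_predicted'")


#: HR-only model of FVC-normalized ventilation for adolescent treadmill data.
MODEL_1 = VentilationModel(-3.859, coef_hr=0.101, name="model1")
#: Two-predictor (HR, f_B) model — the recommended model.
MODEL_2 = VentilationModel(-4.247, coef_hr=0.0595, coef_fb=0.226, name="model2")
#: Breathing-rate-only model.
MODEL_FB_ONLY = VentilationModel(-1.913, coef_fb=0.439, name="fb_only")
#: Two-predictor model normalized to NHANES-III-predicted FVC.
MODEL_2_NHANES = VentilationModel(
    -4.148, coef_hr=0.0535, coef_fb=0.221, fvc_source="nhanes_predicted", name="model2_nhanes"
)


def _subject_field(subject, key, default=None):
    try:
        return subject[key]
    except (KeyError, TypeError, IndexError):
        return getattr(subject, key, default)


def resolve_fvc(subject, model: VentilationModel, fvc: Optional[float] = None) -> float:
    """The FVC normalizer: explicit value, measured, or NHANES-predicted."""
    if fvc is not None:
        return float(fvc)
    if model.fvc_source == "nhanes_predicted":
        pred = predict_lung_function(
            float(_subject_field(subject, "age")),
            float(_subject_field(subject, "height_cm", _subject_field(subject, "height"))),
            int(_subject_field(subject, "sex")),
            str(_subject_field(subject, "race")),
        )
        return float(pred.fvc)
    val = _subject_field(subject, "fvc_L", _subject_field(subject, "fvc_measured"))
    if val is None:
        raise ValueError("subject has no measured FVC and fvc_source is 'measured'")
    return float(val)


def predict_ve(hr, fb=None, fvc: float = 1.0, model: VentilationModel = MODEL_2):
    """Predicted minute ventilation in L·min⁻¹, floored at zero."""
    if fvc <= 0:
        raise ValueError("fvc must be positive")
    hr = np.asarray(hr, dtype=float)
    if model.coef_fb != 0.0:
        if fb is None:
            raise ValueError(f"model {model.name!r} requires a breathing-rate input")
        fb = np.asarray(fb, dtype=float)
    else:
        fb = 0.0
    raw = fvc * (model.intercept + model.coef_hr * hr + model.coef_fb * fb)
    out = np.maximum(raw, 0.0)
    return float(out) if out.ndim == 0 else out


def compute_dose(
    physio: pd.DataFrame,
    conc: pd.DataFrame,
    subject,
    model: VentilationModel = MODEL_2,
    fvc: Optional[float] = None,
) -> Tuple[pd.DataFrame, dict]:
    """Time-resolved inhaled dose of a pollutant for one field session.

    Returns a per-minute dose series (ventilation, inhaled-volume,
    exposure and dose increments, cumulative dose) and a totals dict with
    inhaled volume (m³), exposure (µg·min·m⁻³), dose (µg) and, when the
    subject's weight is known, dose per kg body mass (µg·kg⁻¹).
    """
    c = conc["conc_ugm3"].to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentrations are not allowed")
    t_min = conc["t_min"].to_numpy(dtype=float)
    t_s = physio["t_s"].to_numpy(dtype=float)
    hr = physio["hr_bpm"].to_numpy(dtype=float)
    fb = physio["fb_brpm"].to_numpy(dtype=float) if "fb_brpm" in physio else None

    fvc_val = resolve_fvc(subject, model, fvc)
    ve_s = predict_ve(hr, fb, fvc_val, model)

    # assign each physio second to the 1-minute concentration interval containing it
    rel_min = (t_s - t_s[0]) / 60.0 + t_min[0]
    idx = np.searchsorted(t_min, rel_min, side="right") - 1
    in_interval = (idx >= 0) & (rel_min < t_min[np.clip(idx, 0, None)] + 1.0)
    if not np.all(in_interval):
        gaps = np.unique(np.floor(rel_min[~in_interval]))
        raise ValueError(f"concentration series does not cover physio minutes {gaps.tolist()}")

    n_sec = np.bincount(idx, minlength=len(t_min)).astype(float)
    ve_sum = np.bincount(idx, weights=ve_s, minlength=len(t_min))
    covered = n_sec > 0
    coverage = n_sec / 60.0  # fraction of each minute with physiologic data
    ve_mean = np.zeros(len(t_min))
    ve_mean[covered] = ve_sum[covered] / n_sec[covered]

    volume_inc = ve_mean * coverage / 1000.0  # L/min * min -> m3
    exposure_inc = c * coverage
    dose_inc = c * volume_inc
    series = pd.DataFrame(
        dict(
            t_min=t_min,
            conc_ugm3=c,
            ve_Lmin=ve_mean,
            coverage=coverage,
            volume_increment_m3=volume_inc,
            exposure_increment=exposure_inc,
            dose_increment_ug=dose_inc,
            cumulative_dose_ug=np.cumsum(dose_inc),
        )
    )
    totals = dict(
        inhaled_volume_m3=float(volume_inc.sum()),
        exposure_ug_min_m3=float(exposure_inc.sum()),
        dose_ug=float(dose_inc.sum()),
    )
    weight = _subject_field(subject, "weight_kg", _subject_field(subject, "weight"))
    if weight is not None:
        totals["dose_per_kg_ug"] = totals["dose_ug"] / float(weight)
    return series, totals


def rest_counterfactual(conc: pd.DataFrame, baseline_ve: float, subject=None) -> float:
    """Inhaled dose (µg) had the subject stayed at rest with constant V̇E."""
    if baseline_ve <= 0:
        raise ValueError("baseline ventilation must be positive")
    c = conc["conc_ugm3"].to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValueError("negative concentrations are not allowed")
    return float((c * baseline_ve / 1000.0).sum())
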