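"""Synthetic cohorts, treadmill sessions and field sessions with known truth.

The generator emulates the kind of data a wearable chest strap plus a
respirometer produce during a short treadmill protocol (about a minute at
rest, a minute of walking, a 4-5 minute ramp until heart rate reaches
160-180 beats/min, then a 3-4 minute cool-down), together with Table-1-like
subject morphology and AR(1)-correlated PM2.5 concentration traces for
field sessions.

The ground truth is the linear ventilation model

    V̇E/FVC = beta0 + beta_hr·HR + beta_fb·f_B + b_i + residual,

with a Normal(0, tau²) random intercept b_i per subject. Default fixed
effects are the two-predictor equation the method is built to recover
(-4.247 + 0.0595·HR + 0.226·f_B). The HR→f_B link defaults to
(1.71681, 0.18363), the unique line consistent with both the two-predictor
equation and the HR-only equation (-3.859 + 0.101·HR) under omitted-variable
algebra. Tidal volumes are constructed per breath so that the mean
ventilation over the 1-second rows belonging to each breath interval equals
the model value exactly when tau = sigma = 0; the residual is a
piecewise-constant process on the generator's 30-second reference window,
so the stated sigma is exactly the residual standard deviation of the
primary (30-second) analysis dataset and window residuals are independent;
its amplitude is proportional to the HR-implied demand (ventilation noise
grows with ventilation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .spirometry import predict_lung_function

__all__ = [
    "TruthParams",
    "generate_cohort",
    "simulate_treadmill_session",
    "simulate_field_session",
    "write_study",
]

#: Response level (V̇E/FVC, min⁻¹) at which the residual SD equals sigma.
REF_RESPONSE = 9.5
#: Averaging window (s) over which the residual process is constant; the
#: residual SD of a dataset averaged at this window equals sigma.
REF_WINDOW = 30

RACE_PROBS = {"caucasian": 0.73, "african_american": 0.07, "mexican_american": 0.20}


@dataclass(frozen=True)
class TruthParams:
    """Generative parameters of the ventilation model.

    beta0/beta_hr/beta_fb are the fixed effects of V̇E/FVC on HR and f_B;
    tau is the between-subject SD of the random intercept and sigma the
    residual SD at the 30-second window scale. fb_link maps HR to the mean
    breathing rate; vt_cap_frac caps tidal volume as a fraction of FVC
    (excess ventilation is realized by raising f_B).
    """

    beta0: float = -4.247
    beta_hr: float = 0.0595
    beta_fb: float = 0.226
    tau: float = 0.5
    sigma: float = 1.75
    fb_link: Tuple[float, float] = (1.71681, 0.18363)
    vt_cap_frac: float = 0.65
    seed: int = 0

    def __post_init__(self):
        if self.tau < 0 or self.sigma < 0:
            raise ValueError("tau and sigma must be nonnegative")
        if not 0 < self.vt_cap_frac <= 1:
            raise ValueError("vt_cap_frac must lie in (0, 1]")

    def mean_response(self, hr: np.ndarray, fb: np.ndarray) -> np.ndarray:
        return self.beta0 + self.beta_hr * np.asarray(hr) + self.beta_fb * np.asarray(fb)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(
    n_subjects: int, seed: int, truth: Optional[TruthParams] = None
) -> pd.DataFrame:
    """Draw a cohort of adolescent-athlete-like subjects.

    Ages ~ Normal(17.3, 1.3) truncated to [15, 18]; heights ~ Normal(175, 10);
    40% female; measured FVC is the NHANES-predicted FVC times a
    Normal(0.92, 0.10) percent-predicted factor; FEV1/FVC ~ Normal(0.88,
    0.051) truncated to (0.5, 1]. Each subject carries a Normal(0, tau²)
    random intercept ``b_i``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    truth = truth or TruthParams()
    rng = np.random.default_rng(seed)
    age = _truncated_normal(rng, 17.3, 1.3, 15.0, 18.0, n_subjects)
    height = _truncated_normal(rng, 175.0, 10.0, 140.0, 210.0, n_subjects)
    sex = (rng.random(n_subjects) < 0.4).astype(int)
    races = list(RACE_PROBS)
    race = rng.choice(races, size=n_subjects, p=list(RACE_PROBS.values()))
    bmi = _truncated_normal(rng, 20.6, 2.9, 15.0, 35.0, n_subjects)
    weight = bmi * (height / 100.0) ** 2
    pct_pred = _truncated_normal(rng, 0.92, 0.10, 0.4, 1.6, n_subjects)
    ratio = _truncated_normal(rng, 0.88, 0.051, 0.5001, 1.0, n_subjects)
    b_i = rng.normal(0.0, truth.tau, n_subjects)

    fvc_pred = np.empty(n_subjects)
    fev1_pred = np.empty(n_subjects)
    for i in range(n_subjects):
        pred = predict_lung_function(age[i], height[i], int(sex[i]), str(race[i]))
        fvc_pred[i] = pred.fvc
        fev1_pred[i] = pred.fev1
    fvc = fvc_pred * pct_pred
    fev1 = fvc * ratio

    return pd.DataFrame(
        dict(
            subject_id=[f"S{i + 1:03d}" for i in range(n_subjects)],
            age=age,
            sex=sex,
            height_cm=height,
            weight_kg=weight,
            bmi=bmi,
            race=race,
            fvc_L=fvc,
            fev1_L=fev1,
            fev1_fvc=ratio,
            fvc_pred_L=fvc_pred,
            fev1_pred_L=fev1_pred,
            b_i=b_i,
        )
    )


def _ar1(rng, n, sd, corr_time):
    """Stationary AR(1) series with given marginal SD and correlation time (s)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    phi = np.exp(-1.0 / corr_time)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1 - phi**2), n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i - 1]
    return x


def _treadmill_hr_target(rng):
    """Piecewise HR target for the treadmill protocol; returns (target, segments)."""
    rest = int(np.clip(rng.normal(60, 5), 45, 80))
    walk = int(np.clip(rng.normal(60, 5), 45, 80))
    ramp = int(rng.uniform(240, 300))
    cool = int(rng.uniform(180, 240))
    hr0 = float(np.clip(rng.normal(70, 8), 55, 90))
    peak = float(rng.uniform(160, 180))
    seg_rest = np.full(rest, hr0)
    trans = min(15, walk)
    seg_walk = np.concatenate(
        [np.linspace(hr0, 100.0, trans), np.full(walk - trans, 100.0)]
    )
    seg_ramp = np.linspace(100.0, peak, ramp)
    seg_cool = np.linspace(peak, hr0 + 20.0, cool)
    target = np.concatenate([seg_rest, seg_walk, seg_ramp, seg_cool])
    return target, (rest, walk, ramp, cool)


def _fb_series(rng, hr, truth: TruthParams):
    # f_B deviates from the HR-implied mean by a slow AR(1) drift
    # (breathing-pattern variation independent of heart rate)
    a, s = truth.fb_link
    u = _ar1(rng, len(hr), 4.5, 75.0)
    return np.maximum(8.0, a + s * hr + u)


def simulate_treadmill_session(
    subject, truth: TruthParams, seed: int
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """One treadmill session: (1-second physio records, breath events).

    ``subject`` is a row of :func:`generate_cohort` (mapping-like with
    ``fvc_L`` and ``b_i``).
    """
    fvc = float(subject["fvc_L"])
    if fvc <= 0:
        raise ValueError("subject FVC must be positive")
    b_i = float(subject.get("b_i", 0.0)) if hasattr(subject, "get") else float(subject["b_i"])
    a, s = truth.fb_link
    peak_mu = truth.beta0 + truth.beta_hr * 170.0 + truth.beta_fb * (a + s * 170.0)
    if peak_mu <= 0:
        raise ValueError(
            "truth parameters imply nonpositive ventilation at peak exercise; "
            "raise beta0/beta_hr/beta_fb or adjust fb_link"
        )
    rng = np.random.default_rng(seed)
    target, (rest, walk, ramp, cool) = _treadmill_hr_target(rng)
    n = len(target)
    hr = np.maximum(40.0, target + _ar1(rng, n, 2.0, 10.0))
    fb = _fb_series(rng, hr, truth)

    # activity magnitude by protocol phase (plausible placeholder levels)
    prog = np.linspace(0.0, 1.0, ramp)
    act = np.concatenate(
        [
            np.abs(rng.normal(0.0, 0.01, rest)),
            rng.normal(0.2, 0.03, walk),
            rng.normal(0.4 + 0.4 * prog, 0.05),
            rng.normal(0.3, 0.05, cool),
        ]
    )
    act = np.clip(act, 0.0, None)

    # breath times: spacing 60/f_B seconds, clipped to [1, 10] s
    times = []
    t = 0.0
    while True:
        dt = float(np.clip(60.0 / fb[int(t)], 1.0, 10.0))
        t += dt
        if t >= n:
            break
        times.append(t)
    times = np.asarray(times)
    rows = np.floor(times).astype(int)

    # per-breath interval means over rows (prev_row, this_row]
    starts = np.r_[0, rows[:-1] + 1]
    counts = np.r_[rows[0] + 1, np.diff(rows)]
    end = rows[-1] + 1  # reduceat's final segment must stop at the last breath row
    hr_mean = np.add.reduceat(hr[:end], starts) / counts
    fb_mean = np.add.reduceat(fb[:end], starts) / counts
    # tidal-volume plateau: where the deterministic demand would push V_T
    # past 90% of the cap, raise f_B (single pass) so the realized V_T sits
    # at 90% of the cap instead. The raise depends only on the fixed-effect
    # demand, keeping the recorded f_B independent of the residual noise.
    cap = truth.vt_cap_frac * fvc
    mu_fixed = truth.mean_response(hr_mean, fb_mean)
    vt_demand = fvc * np.maximum(mu_fixed, 0.1) / fb_mean
    over = vt_demand > 0.9 * cap
    if np.any(over):
        mu_base = mu_fixed[over] - truth.beta_fb * fb_mean[over]  # HR part only
        denom = 0.9 * cap - fvc * truth.beta_fb
        if denom <= 0:
            raise ValueError(
                "vt_cap_frac too small relative to beta_fb; raise vt_cap_frac"
            )
        fb_needed = fvc * mu_base / denom
        for j, fbn in zip(np.flatnonzero(over), fb_needed):
            fb[starts[j] : starts[j] + counts[j]] = fbn
        fb_mean = np.add.reduceat(fb[:end], starts) / counts

    mu_det = truth.mean_response(hr_mean, fb_mean) + b_i
    # noise amplitude grows with the HR-implied demand (a deterministic
    # function of HR only, so the noise scale is independent of the f_B
    # deviations and of the subject intercept)
    mu_link = truth.mean_response(hr_mean, a + s * hr_mean)
    scale = np.maximum(mu_link, 0.5) / REF_RESPONSE
    n_blocks = int(np.ceil(n / REF_WINDOW))
    e_series = np.repeat(rng.normal(0.0, 1.0, n_blocks), REF_WINDOW)[:n]
    e_breath = np.add.reduceat(e_series[:end], starts) / counts
    e = e_breath * truth.sigma * scale
    mu = np.maximum(mu_det + e, 0.1)
    vt = np.minimum(fvc * mu / fb_mean, cap)

    physio = pd.DataFrame(
        dict(t_s=np.arange(n, dtype=float), hr_bpm=hr, fb_brpm=fb, act_g=act)
    )
    breaths = pd.DataFrame(dict(t_start_s=times, vt_L=vt))
    return physio, breaths


def simulate_field_session(
    subject,
    truth: TruthParams,
    duration_min: float,
    mean_conc: float,
    seed: int,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """A field exposure session: physiology plus a 1-minute PM2.5 trace.

    The physiologic series alternates rest and activity bouts; the
    concentration is a stationary AR(1) series with the requested mean,
    SD = 0.25·mean and lag-1 correlation 0.8, floored at zero.
    """
    if duration_min < 2:
        raise ValueError("duration must be at least 2 minutes")
    if mean_conc < 0:
        raise ValueError("mean_conc must be nonnegative")
    rng = np.random.default_rng(seed)
    n = int(round(duration_min * 60))

    target = np.empty(n)
    i = 0
    active = False
    while i < n:
        bout = int(rng.uniform(3, 8) * 60)
        level = rng.uniform(120, 170) if active else rng.normal(75, 5)
        target[i : i + bout] = level
        i += bout
        active = not active
    kernel = np.ones(31) / 31.0
    target = np.convolve(np.pad(target, 15, mode="edge"), kernel, mode="valid")
    hr = np.maximum(45.0, target + _ar1(rng, n, 3.0, 10.0))
    fb = _fb_series(rng, hr, truth)
    act = np.clip(0.02 + (hr - 75.0) / 150.0 + rng.normal(0, 0.03, n), 0.0, None)
    physio = pd.DataFrame(
        dict(t_s=np.arange(n, dtype=float), hr_bpm=hr, fb_brpm=fb, act_g=act)
    )

    m = int(round(duration_min))
    if mean_conc == 0:
        conc = np.zeros(m)
    else:
        phi = 0.8
        sd = 0.25 * mean_conc
        x = np.empty(m)
        x[0] = rng.normal(mean_conc, sd)
        innov = rng.normal(0.0, sd * np.sqrt(1 - phi**2), m - 1)
        for k in range(1, m):
            x[k] = mean_conc + phi * (x[k - 1] - mean_conc) + innov[k - 1]
        conc = np.maximum(x, 0.0)
    conc_df = pd.DataFrame(dict(t_min=np.arange(m, dtype=float), conc_ugm3=conc))
    return physio, conc_df


def session_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-session substream seeds derived from one top seed."""
    ss = np.random.SeedSequence(seed)
    return np.array([int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)])


def write_study(
    outdir,
    cohort: pd.DataFrame,
    sessions: Dict[str, Tuple[pd.DataFrame, pd.DataFrame]],
    field: Optional[Dict[str, Tuple[pd.DataFrame, pd.DataFrame]]] = None,
) -> None:
    """Write a complete synthetic study directory (roster + per-subject CSVs)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    roster_cols = [
        "subject_id", "age", "sex", "height_cm", "weight_kg", "race", "fvc_L", "fev1_L",
    ]
    cohort[roster_cols].to_csv(outdir / "roster.csv", index=False)
    cohort.to_csv(outdir / "cohort_full.csv", index=False)
    for sid, (physio, breaths) in sessions.items():
        physio.to_csv(outdir / f"physio_{sid}.csv", index=False)
        breaths.to_csv(outdir / f"breaths_{sid}.csv", index=False)
    for sid, (physio, conc) in (field or {}).items():
        physio.to_csv(outdir / f"field_physio_{sid}.csv", index=False)
        conc.to_csv(outdir / f"field_conc_{sid}.csv", index=False)
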