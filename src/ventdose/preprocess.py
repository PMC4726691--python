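"""Fusing breath events with 1-second physiology and building averaged datasets.

The raw material is two streams: a 1-second record of heart rate (HR),
breathing rate (f_B) and accelerometry (ACT), and a breath-event record
carrying the tidal volume (V_T) of each exhalation stamped at the time the
exhalation began. Each breath is attached to the 1-second row containing
its start time (floor convention; breaths are never split across windows).

From the merged table four analysis datasets can be built: 60-, 30- and
15-second fixed windows aligned to session start, and an "individual
breath" dataset with one record per breath averaging all 1-second values
since the previous breath. Minute ventilation per record is mean tidal
volume times mean breathing rate (V̇E = V_T·f_B), i.e. the mean volumetric
flow rate over the averaging period; V̇E and V_T are additionally
normalized by the subject's FVC. A dichotomous "warm" flag separates the
warm-up (rising HR) from the cool-down (falling HR) phase.
"""

from __future__ import annotations

import logging
from typing import Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TIMEBASES",
    "merge_breaths",
    "build_averaged_dataset",
    "compute_warm",
]

#: Supported averaging time bases: fixed window lengths in seconds, or
#: ``"ib"`` for the individual-breath dataset.
TIMEBASES = {"60": 60, "30": 30, "15": 15, "ib": None}

WARM_SMOOTH_SECONDS = 15

PHYSIO_COLUMNS = ["t_s", "hr_bpm", "fb_brpm", "act_g"]
BREATH_COLUMNS = ["t_start_s", "vt_L"]


def _normalize_timebase(timebase) -> Optional[int]:
    key = str(timebase)
    if key not in TIMEBASES:
        raise ValueError(f"timebase must be one of {sorted(TIMEBASES)}, got {timebase!r}")
    return TIMEBASES[key]


def merge_breaths(physio: pd.DataFrame, breaths: pd.DataFrame) -> pd.DataFrame:
    """Attach each breath's V_T to the 1-second row containing its start.

    Rows without a breath carry NaN in the ``vt_L`` column. Two breaths
    flooring to the same second have their volumes summed on that row.
    Total attached volume equals the total input volume exactly.
    """
    physio = physio.reset_index(drop=True)
    t = physio["t_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.allclose(np.diff(t), 1.0):
        raise ValueError("physio records must be at strict 1-second spacing")
    merged = physio.copy()
    vt = np.full(len(physio), np.nan)
    if len(breaths) == 0:
        logger.warning("merge_breaths: empty breath list; V_T is all-missing")
        merged["vt_L"] = vt
        return merged
    t0 = t[0]
    starts = breaths["t_start_s"].to_numpy(dtype=float)
    vols = breaths["vt_L"].to_numpy(dtype=float)
    rows = np.floor(starts - t0).astype(int)
    bad = (rows < 0) | (rows >= len(t))
    if np.any(bad):
        raise ValueError(
            f"breath events outside the physio time span at t={starts[bad].tolist()}"
        )
    sums = np.zeros(len(physio))
    np.add.at(sums, rows, vols)
    has = np.zeros(len(physio), dtype=bool)
    has[rows] = True
    vt[has] = sums[has]
    merged["vt_L"] = vt
    return merged


def compute_warm(hr: np.ndarray) -> np.ndarray:
    """0 while HR is still climbing to its (smoothed) session maximum, 1 after.

    HR is smoothed with a centered 15-second rolling mean; the flag flips
    the sample after the last occurrence of the smoothed maximum, so a
    constant series is all zero.
    """
    hr = np.asarray(hr, dtype=float)
    if len(hr) < WARM_SMOOTH_SECONDS:
        raise ValueError(
            f"series of length {len(hr)} is shorter than the {WARM_SMOOTH_SECONDS}-s smoothing window"
        )
    smooth = (
        pd.Series(hr).rolling(WARM_SMOOTH_SECONDS, center=True, min_periods=1).mean().to_numpy()
    )
    peak = len(smooth) - 1 - int(np.argmax(smooth[::-1]))  # last index of the max
    warm = np.zeros(len(hr), dtype=int)
    warm[peak + 1 :] = 1
    return warm


def build_averaged_dataset(
    merged: pd.DataFrame,
    fvc: float,
    timebase: Union[int, str],
    subject_id: Optional[str] = None,
    ve_mode: str = "mean_vt_times_fb",
) -> pd.DataFrame:
    """Build one time-averaged analysis dataset from a merged 1-second table.

    Parameters
    ----------
    merged : output of :func:`merge_breaths`.
    fvc : the subject's forced vital capacity in liters (normalizer).
    timebase : 60, 30 or 15 (seconds) for fixed windows, or ``"ib"`` for
        the individual-breath dataset.
    ve_mode : ``"mean_vt_times_fb"`` computes V̇E as mean V_T times mean
        f_B (the primary definition); ``"volume_rate"`` computes it as
        total attached volume divided by window duration, for sensitivity
        checks.

    Fixed windows are aligned to the session start; windows containing no
    breath are dropped (V̇E is undefined there) and logged.
    """
    if fvc <= 0:
        raise ValueError("fvc must be positive")
    if ve_mode not in ("mean_vt_times_fb", "volume_rate"):
        raise ValueError(f"unknown ve_mode {ve_mode!r}")
    if len(merged) == 0:
        raise ValueError("merged table is empty")
    window = _normalize_timebase(timebase)

    merged = merged.reset_index(drop=True)
    t = merged["t_s"].to_numpy(dtype=float)
    hr = merged["hr_bpm"].to_numpy(dtype=float)
    fb = merged["fb_brpm"].to_numpy(dtype=float)
    act = merged["act_g"].to_numpy(dtype=float)
    vt = merged["vt_L"].to_numpy(dtype=float)
    warm = compute_warm(hr)
    rel = t - t[0]

    records = []
    if window is not None:
        edges = np.arange(0.0, rel[-1] + window, window)
        idx = np.minimum((rel // window).astype(int), len(edges) - 1)
        n_dropped = 0
        for w in range(idx.max() + 1):
            sel = idx == w
            vt_vals = vt[sel]
            vt_vals = vt_vals[~np.isnan(vt_vals)]
            if len(vt_vals) == 0:
                n_dropped += 1
                continue
            vt_mean = vt_vals.mean()
            fb_mean = fb[sel].mean()
            dur = float(sel.sum())
            if ve_mode == "mean_vt_times_fb":
                ve = vt_mean * fb_mean
            else:
                ve = vt_vals.sum() / (dur / 60.0)
            records.append(
                dict(
                    window_start_s=float(w * window),
                    window_dur_s=dur,
                    hr=hr[sel].mean(),
                    fb=fb_mean,
                    act=act[sel].mean(),
                    vt=vt_mean,
                    ve=ve,
                    warm=int(warm[sel].mean() >= 0.5),
                )
            )
        if n_dropped:
            logger.info("build_averaged_dataset: dropped %d windows with no breaths", n_dropped)
    else:
        # individual-breath dataset: one record per breath after the first,
        # averaging 1-second rows since (exclusive) the previous breath row.
        breath_rows = np.flatnonzero(~np.isnan(vt))
        for prev, cur in zip(breath_rows[:-1], breath_rows[1:]):
            sel = slice(prev + 1, cur + 1)
            fb_mean = fb[sel].mean()
            dur = float(cur - prev)
            if ve_mode == "mean_vt_times_fb":
                ve = vt[cur] * fb_mean
            else:
                ve = vt[cur] / (dur / 60.0)
            records.append(
                dict(
                    window_start_s=float(rel[prev + 1]),
                    window_dur_s=dur,
                    hr=hr[sel].mean(),
                    fb=fb_mean,
                    act=act[sel].mean(),
                    vt=vt[cur],
                    ve=ve,
                    warm=int(warm[cur]),
                )
            )

    out = pd.DataFrame.from_records(records)
    if len(out) == 0:
        return out
    out["ve_norm"] = out["ve"] / fvc
    out["vt_norm"] = out["vt"] / fvc
    if subject_id is not None:
        out.insert(0, "subject_id", str(subject_id))
    return out
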