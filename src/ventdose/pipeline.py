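"""End-to-end reproducible pipeline: simulate → preprocess → fit → select → dose.

One top-level seed drives every stochastic stage through deterministically
derived substreams, so re-running an identical configuration reproduces
every numeric output bit for bit. A manifest records the seed, a hash of
the configuration, per-stage row counts and a content hash of every file
written.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import dose as dose_mod
from .lmm import fit_lmm
from .preprocess import TIMEBASES, build_averaged_dataset, merge_breaths
from .selection import cv_percent_error, evaluate_subsets, select_best
from .spirometry import predict_lung_function
from .synthetic import TruthParams, generate_cohort, session_seeds, simulate_field_session, simulate_treadmill_session

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "DEFAULT_POOL",
    "simulate_study",
    "make_analysis_table",
    "run_pipeline",
]

#: The nine candidate predictors of FVC-normalized minute ventilation.
DEFAULT_POOL = ["hr", "fb", "act", "warm", "age", "sex", "bmi", "fev1_fvc", "height"]

_MODEL_CHOICES = {
    "1": dose_mod.MODEL_1,
    "2": dose_mod.MODEL_2,
    "fb_only": dose_mod.MODEL_FB_ONLY,
    "2_nhanes": dose_mod.MODEL_2_NHANES,
}


@dataclass
class RunConfig:
    """Configuration of a full synthetic-study pipeline run."""

    seed: int = 0
    n_subjects: int = 15
    timebase: str = "30"
    response: str = "ve_norm"
    predictor_pool: List[str] = field(default_factory=lambda: list(DEFAULT_POOL))
    k_folds: int = 5
    dose_model: str = "2"
    max_subset_size: Optional[int] = None
    field_duration_min: float = 105.0
    field_mean_conc: float = 3.9
    out_dir: str = "ventdose_run"

    def validate(self) -> List[str]:
        problems = []
        if self.k_folds < 2:
            problems.append("k_folds must be at least 2")
        if self.k_folds > self.n_subjects:
            problems.append("k_folds cannot exceed n_subjects")
        if str(self.timebase) not in TIMEBASES:
            problems.append(f"timebase must be one of {sorted(TIMEBASES)}")
        if self.response not in ("ve_norm", "ve_over_fev1"):
            problems.append("response must be 've_norm' or 've_over_fev1'")
        if self.dose_model not in _MODEL_CHOICES:
            problems.append(f"dose_model must be one of {sorted(_MODEL_CHOICES)}")
        if self.n_subjects < 2:
            problems.append("n_subjects must be at least 2")
        if not self.predictor_pool:
            problems.append("predictor_pool is empty")
        return problems

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def simulate_study(
    n_subjects: int, seed: int, truth: Optional[TruthParams] = None
) -> Tuple[pd.DataFrame, Dict[str, Tuple[pd.DataFrame, pd.DataFrame]]]:
    """Cohort plus one treadmill session per subject, from one seed."""
    truth = truth or TruthParams()
    seeds = session_seeds(seed, n_subjects + 1)
    cohort = generate_cohort(n_subjects, int(seeds[0]), truth)
    sessions = {}
    for i, row in enumerate(cohort.itertuples(index=False)):
        physio, breaths = simulate_treadmill_session(
            cohort.iloc[i], truth, int(seeds[i + 1])
        )
        sessions[row.subject_id] = (physio, breaths)
    return cohort, sessions


def make_analysis_table(
    cohort: pd.DataFrame,
    sessions: Dict[str, Tuple[pd.DataFrame, pd.DataFrame]],
    timebase: str = "30",
) -> pd.DataFrame:
    """Merge, average and join subject covariates into one modeling table.

    Adds the two response variants (V̇E/FVC and V̇E/FEV1) plus V̇E
    normalized to the NHANES-predicted FVC.
    """
    frames = []
    cohort = cohort.set_index("subject_id", drop=False)
    for sid, (physio, breaths) in sessions.items():
        subj = cohort.loc[sid]
        merged = merge_breaths(physio, breaths)
        avg = build_averaged_dataset(merged, float(subj["fvc_L"]), timebase, subject_id=sid)
        if len(avg) == 0:
            logger.warning("subject %s produced no averaged records; dropped", sid)
            continue
        avg["ve_over_fev1"] = avg["ve"] / float(subj["fev1_L"])
        if "fvc_pred_L" in subj:
            avg["ve_norm_pred"] = avg["ve"] / float(subj["fvc_pred_L"])
        for col in ("age", "sex", "bmi", "fev1_fvc"):
            avg[col] = float(subj[col])
        avg["height"] = float(subj["height_cm"])
        frames.append(avg)
    return pd.concat(frames, ignore_index=True)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write a run directory with a manifest."""
    problems = config.validate()
    if problems:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(problems))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = TruthParams()
    counts: Dict[str, int] = {}

    # stage 1: simulate
    cohort, sessions = simulate_study(config.n_subjects, config.seed, truth)
    roster_cols = ["subject_id", "age", "sex", "height_cm", "weight_kg", "race", "fvc_L", "fev1_L"]
    cohort[roster_cols].to_csv(out / "roster.csv", index=False)
    counts["subjects"] = len(cohort)

    # stage 2: preprocess
    table = make_analysis_table(cohort, sessions, config.timebase)
    table.to_csv(out / f"averaged_{config.timebase}s.csv", index=False)
    counts["averaged_records"] = len(table)

    # stage 3: fit the recommended two-predictor model
    fit = fit_lmm(table, ["hr", "fb"], response=config.response)
    (out / "model_fit.json").write_text(json.dumps(fit.to_dict(), indent=2))
    counts["model_coefficients"] = len(fit.params)

    # stage 4: cross-validation of the fitted model
    cv = cv_percent_error(
        table, ["hr", "fb"], k=config.k_folds, seed=config.seed, response=config.response
    )
    (out / "crossval.json").write_text(
        json.dumps(
            dict(
                predictors=list(cv.predictors),
                seed=cv.seed,
                fold_map={str(k): int(v) for k, v in cv.fold_map.items()},
                mean_pe=cv.mean_pe,
                sd_pe=cv.sd_pe,
                n_validation_obs=int(len(cv.percent_errors)),
            ),
            indent=2,
        )
    )
    counts["cv_validation_obs"] = int(len(cv.percent_errors))

    # stage 5: brute-force subset selection
    sizes = None
    if config.max_subset_size is not None:
        sizes = list(range(1, config.max_subset_size + 1))
    sel = evaluate_subsets(
        table, config.predictor_pool, response=config.response,
        k=config.k_folds, seed=config.seed, sizes=sizes,
    )
    sel_out = sel.drop(columns=["estimates"])
    sel_out.to_csv(out / "selection_table.csv", index=False)
    winners = {}
    for size in sorted(sel["size"].unique()):
        _, report = select_best(sel, int(size))
        winners[str(int(size))] = report
    (out / "selection_winners.json").write_text(json.dumps(winners, indent=2))
    counts["models_evaluated"] = len(sel)

    # stage 6: dose on one synthetic field session (first subject)
    subj = cohort.iloc[0]
    fseed = int(session_seeds(config.seed + 1, 1)[0])
    physio_f, conc = simulate_field_session(
        subj, truth, config.field_duration_min, config.field_mean_conc, fseed
    )
    model = _MODEL_CHOICES[config.dose_model]
    series, totals = dose_mod.compute_dose(physio_f, conc, subj, model)
    series.to_csv(out / "dose_series.csv", index=False)
    (out / "dose_totals.json").write_text(json.dumps(totals, indent=2))
    counts["dose_intervals"] = len(series)

    manifest = dict(
        seed=config.seed,
        config=asdict(config),
        config_hash=config.config_hash(),
        stage_row_counts=counts,
        files={p.name: _hash_file(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"},
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
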