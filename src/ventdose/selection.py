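"""Brute-force predictor-subset evaluation with subject-grouped k-fold CV.

Every non-empty subset of the candidate predictors is fit to the full data
(for AIC and Wald p-values) and scored by subject-grouped k-fold
cross-validation: folds partition SUBJECTS, each fold's model is fit on
the training subjects only, and held-out observations are predicted with
fixed effects alone (a new subject has no estimated random intercept).
Validation percent errors 100·(prediction - observation)/observation are
pooled over observations across all folds; their mean and SD summarize a
model's predictive performance.

The best model of a given size is chosen by a three-criteria cascade:
a model minimizing both |mean percent error| and AIC wins outright;
otherwise the percent-error winner and the AIC winner are compared on the
confidence in their estimates — the candidate whose worst coefficient
p-value is smaller wins — with any remaining tie broken by smaller
|mean percent error|.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .lmm import LMMData, predict

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "enumerate_subsets",
    "grouped_kfold",
    "cv_percent_error",
    "evaluate_subsets",
    "select_best",
]

ALPHA = 0.05


@dataclass
class CVResult:
    """Pooled cross-validation percent errors for one predictor subset."""

    predictors: tuple
    fold_map: Dict[object, int]
    seed: int
    percent_errors: np.ndarray
    mean_pe: float
    sd_pe: float


def enumerate_subsets(predictor_names: Sequence[str]) -> list[tuple]:
    """All non-empty predictor subsets, in size-then-lexicographic order."""
    names = list(predictor_names)
    if not names:
        raise ValueError("predictor list is empty")
    if len(set(names)) != len(names):
        raise ValueError("predictor names must be unique")
    if len(names) > 20:
        raise ValueError("more than 20 candidate predictors; enumeration refused")
    subsets = []
    for size in range(1, len(names) + 1):
        subsets.extend(sorted(itertools.combinations(sorted(names), size)))
    # keep each subset's internal order as supplied, not alphabetical
    order = {c: i for i, c in enumerate(names)}
    return [tuple(sorted(s, key=order.get)) for s in subsets]


def grouped_kfold(subject_ids: Sequence, k: int, seed: int) -> Dict[object, int]:
    """Randomly partition subjects into k folds, as equal as possible."""
    ids = sorted(set(subject_ids), key=str)  # row-order invariant
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(ids)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    sizes = np.full(k, len(ids) // k)
    sizes[: len(ids) % k] += 1
    fold_map = {}
    pos = 0
    for fold, size in enumerate(sizes):
        for j in perm[pos : pos + size]:
            fold_map[ids[j]] = fold
        pos += size
    return fold_map


def cv_percent_error(
    data: pd.DataFrame,
    predictors: Sequence[str],
    k: int = 5,
    seed: int = 0,
    response: str = "ve_norm",
    groups: str = "subject_id",
    lmm_data: Optional[LMMData] = None,
    fold_map: Optional[Dict[object, int]] = None,
) -> CVResult:
    """Subject-grouped k-fold cross-validation percent error for one subset."""
    predictors = list(predictors)
    if lmm_data is None:
        lmm_data = LMMData(data, predictors, response, groups)
    if fold_map is None:
        fold_map = grouped_kfold(data[groups].tolist(), k, seed)
    subjects = list(lmm_data.subjects)
    n_folds = max(fold_map.values()) + 1
    errors = []
    for fold in range(n_folds):
        val = [s for s in subjects if fold_map[s] == fold]
        train = [s for s in subjects if fold_map[s] != fold]
        assert not set(train) & set(val), "grouped CV leaked a subject across folds"
        if len(train) < 2:
            raise ValueError("each training set must contain at least 2 subjects")
        fit = lmm_data.fit(predictors=predictors, subjects=train)
        val_rows = data[data[groups].isin(val)]
        obs = val_rows[response].to_numpy(float)
        if np.any(obs <= 0):
            raise ValueError(
                "validation observations must be positive (percent error undefined)"
            )
        pred = predict(fit, val_rows)
        errors.append(100.0 * (pred - obs) / obs)
    pooled = np.concatenate(errors)
    return CVResult(
        predictors=tuple(predictors),
        fold_map=dict(fold_map),
        seed=seed,
        percent_errors=pooled,
        mean_pe=float(pooled.mean()),
        sd_pe=float(pooled.std(ddof=1)),
    )


def evaluate_subsets(
    data: pd.DataFrame,
    pool: Sequence[str],
    response: str = "ve_norm",
    k: int = 5,
    seed: int = 0,
    sizes: Optional[Sequence[int]] = None,
    groups: str = "subject_id",
) -> pd.DataFrame:
    """Fit and cross-validate predictor subsets; one table row per subset.

    One fold split (from ``seed``) is reused across all subsets so their
    percent errors are comparable. ``sizes`` restricts the enumeration to
    the given subset sizes (default: all).
    """
    pool = list(pool)
    lmm_data = LMMData(data, pool, response, groups)
    fold_map = grouped_kfold(data[groups].tolist(), k, seed)
    subsets = enumerate_subsets(pool)
    if sizes is not None:
        keep = set(sizes)
        subsets = [s for s in subsets if len(s) in keep]
    rows = []
    for subset in subsets:
        fit = lmm_data.fit(predictors=list(subset))
        try:
            cv = cv_percent_error(
                data, list(subset), k=k, seed=seed, response=response,
                groups=groups, lmm_data=lmm_data, fold_map=fold_map,
            )
            mean_pe, sd_pe = cv.mean_pe, cv.sd_pe
        except ValueError as exc:
            # e.g. a between-subject predictor constant within a training
            # fold; the subset keeps its full-data fit but has no CV score
            logger.warning("no CV score for %s: %s", "+".join(subset), exc)
            mean_pe = sd_pe = float("nan")
        rows.append(
            dict(
                predictors="+".join(subset),
                size=len(subset),
                aic=fit.aic,
                mean_pe=mean_pe,
                sd_pe=sd_pe,
                all_significant=bool((fit.pvalues < ALPHA).all()),
                max_pvalue=float(fit.pvalues.max()),
                tau2=fit.tau2,
                sigma2=fit.sigma2,
                estimates={k_: float(v) for k_, v in fit.params.items()},
            )
        )
    table = pd.DataFrame(rows)
    table.attrs["seed"] = seed
    table.attrs["k"] = k
    return table


def select_best(table: pd.DataFrame, n_predictors: int) -> tuple[pd.Series, dict]:
    """Choose the best model of a given size by the three-criteria cascade.

    Returns the winning table row and a machine-readable report stating
    which criterion decided.
    """
    rows = table[table["size"] == n_predictors]
    if len(rows) == 0:
        raise ValueError(f"no evaluated models with {n_predictors} predictors")
    abs_pe = rows["mean_pe"].abs()
    pe_ix = abs_pe.idxmin() if abs_pe.notna().any() else rows["aic"].idxmin()
    aic_ix = rows["aic"].idxmin()
    if pe_ix == aic_ix:
        ix = pe_ix
        reason = "minimizes both |mean percent error| and AIC"
    else:
        pe_row, aic_row = rows.loc[pe_ix], rows.loc[aic_ix]
        if pe_row["max_pvalue"] != aic_row["max_pvalue"]:
            ix = pe_ix if pe_row["max_pvalue"] < aic_row["max_pvalue"] else aic_ix
            reason = (
                "percent error and AIC disagree; chose the candidate with the "
                "higher confidence in its estimates (smaller worst-case p-value)"
            )
        else:
            pe_a = np.nan_to_num(abs(pe_row["mean_pe"]), nan=np.inf)
            pe_b = np.nan_to_num(abs(aic_row["mean_pe"]), nan=np.inf)
            ix = pe_ix if pe_a <= pe_b else aic_ix
            reason = (
                "percent error and AIC disagree with equally confident "
                "estimates; chose by smaller |mean percent error|"
            )
    row = table.loc[ix]
    report = dict(
        size=int(n_predictors),
        predictors=row["predictors"],
        criterion=reason,
        mean_pe=float(row["mean_pe"]),
        aic=float(row["aic"]),
        all_significant=bool(row["all_significant"]),
        max_pvalue=float(row["max_pvalue"]),
    )
    return row, report
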