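"""Cross-validated AUC evaluation of algorithmic, clinical and combined scores.

The algorithmic score is evaluated with k-fold cross-validation (default
k = 10): each fold's lookup table is built on the other 90% of assessments
and scores the held-out 10%, so no assessment ever contributes to its own
lookup table; the headline statistic is the mean AUC over folds.  The 0-4
clinical rating is a single whole-set AUC (it involves no fitting).  The
combined score is an ordinary-least-squares fit of the binary outcome on
intercept + algorithmic score + clinical rating, refit inside each training
fold and applied to the held-out rows.

AUC is the rank-based (Mann-Whitney) statistic with half-credit for ties —
integer-valued scores tie often, so the correction matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chapters import FrequencyMatrix
from .risk_model import MODELS, Mode, Variant, build_lookup, score_matrix

logger = logging.getLogger(__name__)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC of ``scores`` against binary ``labels``.

    Equals the mean over all (positive, negative) pairs of
    1[s+ > s-] + 0.5 * 1[s+ == s-].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both label classes to be present")
    ranks = stats.rankdata(scores)  # average ranks implement the tie half-credit
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class FoldPlan:
    """A k-fold partition of n assessments.

    ``assignment[i]`` is the fold id (0..k-1) of assessment i.  Folds are
    disjoint, cover everything and (for the assessment unit) differ in size
    by at most one.
    """

    k: int
    assignment: np.ndarray
    seed: int
    unit: str = "assessment"

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)


def make_folds(
    n: int,
    k: int = 10,
    seed: int = 0,
    unit: str = "assessment",
    patient_ids: np.ndarray | None = None,
) -> FoldPlan:
    """Seeded random k-fold plan over ``n`` assessments.

    With ``unit="patient"`` all of a patient's assessments land in one fold
    (guarding against same-patient train/test leakage); fold sizes are then
    only approximately balanced.
    """
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if n < k:
        raise ValueError(f"cannot split {n} assessments into {k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=np.int64)
    if unit == "assessment":
        perm = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            assignment[chunk] = fold
    elif unit == "patient":
        if patient_ids is None:
            raise ValueError("patient-unit folds require patient_ids")
        patient_ids = np.asarray(patient_ids)
        uniq = rng.permutation(np.unique(patient_ids))
        sizes = pd.Series(patient_ids).value_counts()
        load = np.zeros(k, dtype=np.int64)
        fold_of = {}
        for pid in uniq:  # greedy: largest-load-last keeps folds near-balanced
            f = int(load.argmin())
            fold_of[pid] = f
            load[f] += int(sizes[pid])
        assignment = np.array([fold_of[p] for p in patient_ids], dtype=np.int64)
    else:
        raise ValueError(f"unit must be 'assessment' or 'patient', got {unit!r}")
    return FoldPlan(k=k, assignment=assignment, seed=seed, unit=unit)


@dataclass
class LinearCombiner:
    """OLS combination of algorithmic and clinical scores against the outcome."""

    intercept: float
    coef_algorithm: float
    coef_clinical: float
    dropped: str | None = None  # covariate dropped for rank deficiency, if any

    def predict(self, alg: np.ndarray, clin: np.ndarray) -> np.ndarray:
        return (
            self.intercept
            + self.coef_algorithm * np.asarray(alg, dtype=float)
            + self.coef_clinical * np.asarray(clin, dtype=float)
        )


def fit_combined(
    train_alg: np.ndarray, train_clin: np.ndarray, train_labels: np.ndarray
) -> LinearCombiner:
    """Least-squares fit of the binary outcome on the two score covariates.

    If one covariate is constant (rank-deficient design) it is dropped with a
    warning and the fit falls back to the remaining one.
    """
    alg = np.asarray(train_alg, dtype=float)
    clin = np.asarray(train_clin, dtype=float)
    y = np.asarray(train_labels, dtype=float)
    if not (alg.shape == clin.shape == y.shape):
        raise ValueError("training vectors must be aligned")
    use_alg = np.ptp(alg) > 0
    use_clin = np.ptp(clin) > 0
    dropped = None
    cols = [np.ones_like(y)]
    if use_alg:
        cols.append(alg)
    else:
        dropped = "algorithm"
        logger.warning("algorithm score is constant on this training set; dropped")
    if use_clin:
        cols.append(clin)
    else:
        dropped = "clinical" if dropped is None else "both"
        logger.warning("clinical score is constant on this training set; dropped")
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    it = iter(beta[1:])
    return LinearCombiner(
        intercept=float(beta[0]),
        coef_algorithm=float(next(it)) if use_alg else 0.0,
        coef_clinical=float(next(it)) if use_clin else 0.0,
        dropped=dropped,
    )


def apply_combined(
    combiner: LinearCombiner, alg: np.ndarray, clin: np.ndarray
) -> np.ndarray:
    """RiskScore_Combined: the fitted linear predictor on (test) rows."""
    return combiner.predict(alg, clin)


def evaluate_clinical(clinical: np.ndarray, labels: np.ndarray) -> float:
    """Whole-set AUC of the 0-4 clinical rating (no cross-validation)."""
    clinical = np.asarray(clinical)
    if not np.isin(clinical, [0, 1, 2, 3, 4]).all():
        raise ValueError("clinical ratings must be integers 0..4")
    return auc(clinical, labels)


@dataclass
class EvaluationReport:
    """Per-model cross-validated AUCs plus the clinical baseline.

    ``fold_detail`` has one row per (model, fold) with the algorithm and
    combined AUCs; ``mean_algorithm`` / ``mean_combined`` average the
    non-skipped folds.  ``to_table()`` renders the familiar three-column
    summary (algorithm / clinical / combined per history length).
    """

    mean_algorithm: dict[str, float]
    mean_combined: dict[str, float]
    clinical_auc: float
    fold_detail: pd.DataFrame
    combiner_coefficients: pd.DataFrame
    skipped_folds: list[tuple[str, int, str]]
    config: dict = field(default_factory=dict)

    def to_table(self, ndigits: int = 2) -> pd.DataFrame:
        rows = []
        names = {
            "tau1": "0-3 months (tau=1)",
            "tau2": "0-6 months (tau=2)",
            "tau3": "0-12 months (tau=3)",
            "tau4": "0-24 months (tau=4)",
            "tau5": "0-48 months (tau=5)",
            "combined": "Combined tau (1..5)",
        }
        for model in MODELS:
            rows.append(
                {
                    "history": names[model],
                    "auc_algorithm": round(self.mean_algorithm[model], ndigits),
                    "auc_clinical": round(self.clinical_auc, ndigits),
                    "auc_combined": round(self.mean_combined[model], ndigits),
                }
            )
        return pd.DataFrame(rows)


def cross_validate(
    F: FrequencyMatrix,
    clinical: np.ndarray,
    labels: np.ndarray,
    plan: FoldPlan,
    variant: Variant = "normalized-ratio",
    theta: float = 0.5,
    mode: Mode = "binary",
    models: tuple[str, ...] = MODELS,
) -> EvaluationReport:
    """Cross-validated evaluation of every scoring model.

    For each fold and model: build the lookup table on the out-of-fold
    assessments, score the held-out ones, record the algorithm AUC; fit the
    OLS combiner on the training fold (scores from that same fold's table)
    and record the combined AUC.  Folds whose training part lacks a class, or
    whose test part is single-class, are skipped with a warning and listed in
    the report.
    """
    labels = np.asarray(labels)
    clinical = np.asarray(clinical)
    n = F.n_assessments
    if not (len(labels) == len(clinical) == len(plan.assignment) == n):
        raise ValueError("frequency matrix, scores, labels and plan must align")

    fold_rows = []
    coef_rows = []
    skipped: list[tuple[str, int, str]] = []
    clinical_auc = evaluate_clinical(clinical, labels)

    for fold in range(plan.k):
        test = plan.fold_indices(fold)
        train = np.flatnonzero(plan.assignment != fold)
        if len(np.unique(labels[train])) < 2:
            for model in models:
                skipped.append((model, fold, "single-class training fold"))
            logger.warning("fold %d skipped: single-class training data", fold)
            continue
        if len(np.unique(labels[test])) < 2:
            for model in models:
                skipped.append((model, fold, "single-class test fold"))
            logger.warning("fold %d skipped: single-class test data", fold)
            continue
        F_train = FrequencyMatrix(
            values=F.values[train], assessment_ids=F.assessment_ids[train]
        )
        table = build_lookup(F_train, labels[train], variant=variant, theta=theta)
        for model in models:
            s_train = score_matrix(F.values[train], table, model=model, mode=mode)
            s_test = score_matrix(F.values[test], table, model=model, mode=mode)
            a_alg = auc(s_test, labels[test])
            combiner = fit_combined(s_train, clinical[train], labels[train])
            s_comb = apply_combined(combiner, s_test, clinical[test])
            a_comb = auc(s_comb, labels[test])
            fold_rows.append(
                {
                    "model": model,
                    "fold": fold,
                    "n_test": len(test),
                    "auc_algorithm": a_alg,
                    "auc_combined": a_comb,
                }
            )
            coef_rows.append(
                {
                    "model": model,
                    "fold": fold,
                    "intercept": combiner.intercept,
                    "coef_algorithm": combiner.coef_algorithm,
                    "coef_clinical": combiner.coef_clinical,
                }
            )

    detail = pd.DataFrame(fold_rows)
    if detail.empty:
        raise ValueError("every fold was degenerate; nothing to report")
    means_alg = detail.groupby("model")["auc_algorithm"].mean()
    means_comb = detail.groupby("model")["auc_combined"].mean()
    return EvaluationReport(
        mean_algorithm={m: float(means_alg[m]) for m in models if m in means_alg},
        mean_combined={m: float(means_comb[m]) for m in models if m in means_comb},
        clinical_auc=clinical_auc,
        fold_detail=detail,
        combiner_coefficients=pd.DataFrame(coef_rows),
        skipped_folds=skipped,
        config={
            "k": plan.k,
            "seed": plan.seed,
            "unit": plan.unit,
            "variant": variant,
            "theta": theta,
            "mode": mode,
        },
    )
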