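"""Validation of habitat model predictions on held-out coastline points.

Three statistics summarise a model, following standard distribution-model
practice: AUC (threshold-free ranking accuracy), and sensitivity and
specificity at a habitat-specific cut-off chosen to maximise their sum.
AUC bands follow Swets: > 0.9 highly accurate, 0.7-0.9 useful, < 0.7 poor,
<= 0.5 no predictive power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .hdm_fit import DegenerateSampleError, fit_logistic, build_design, predict_prob, select_model_aic
from .sampling import random_split, sample_size

ACCURACY_BANDS = ("highly_accurate", "useful", "poor", "no_power")


@dataclass
class EvaluationResult:
    """Test-split performance of one fitted habitat model."""

    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy_band: str
    train_prevalence: float | None = None

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class NullSummary:
    """Mean and SD of performance metrics over random-split replicates."""

    mean: dict
    sd: dict
    n_reps: int
    n_degenerate: int


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined: labels contain a single class")
    return labels


def roc_auc(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, rank (Mann-Whitney) formulation.

    Equals the probability that a random presence point outranks a random
    absence point; tied probabilities count 1/2 per tied pair.
    """
    probs = np.asarray(probs, float)
    labels = _check_binary(labels)
    r = rankdata(probs)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = r[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _threshold_candidates(probs: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct probabilities plus boundaries.

    With the >= classification rule these candidates realise every
    achievable confusion matrix: below-minimum (everything presence),
    each inter-probability gap, above-maximum (everything absence).
    """
    u = np.unique(probs)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate(([u[0] / 2.0], mids, [(u[-1] + 1.0) / 2.0]))


def optimal_threshold(probs: Sequence[float], labels: Sequence[int]) -> float:
    """Cut-off maximising sensitivity + specificity (presence when p >= t).

    Ties in the achieved sum resolve to the smallest such threshold,
    favouring sensitivity (detecting presences).
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(_check_binary(labels))
    cands = _threshold_candidates(probs)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    # sweep: for each candidate t, tp = #presences with prob >= t
    order = np.argsort(probs)
    sp = probs[order]
    sl = labels[order]
    # positives/negatives with prob < t, via searchsorted on the sorted probs
    cum_pos = np.concatenate(([0], np.cumsum(sl)))
    idx = np.searchsorted(sp, cands, side="left")
    pos_below = cum_pos[idx]
    neg_below = idx - pos_below
    se = (n_pos - pos_below) / n_pos
    spe = neg_below / n_neg
    score = se + spe
    best = np.flatnonzero(score == score.max())[0]  # smallest candidate wins ties
    return float(cands[best])


def confusion_stats(
    probs: Sequence[float],
    labels: Sequence[int],
    threshold: float,
    train_prevalence: float | None = None,
) -> EvaluationResult:
    """Confusion counts and se/spe at a threshold (presence when p >= t).

    The AUC and band fields are filled by `evaluate_predictions`; here
    they are placeholders (nan / empty) so partial use stays explicit.
    """
    probs = np.asarray(probs, float)
    labels = np.asarray(labels)
    pred = probs >= threshold
    obs = labels == 1
    tp = int(np.sum(pred & obs))
    fp = int(np.sum(pred & ~obs))
    tn = int(np.sum(~pred & ~obs))
    fn = int(np.sum(~pred & obs))
    se = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    return EvaluationResult(
        auc=float("nan"), threshold=float(threshold),
        sensitivity=se, specificity=spe,
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy_band="", train_prevalence=train_prevalence,
    )


def accuracy_band(auc: float) -> str:
    """Swets accuracy band for an AUC value."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC outside [0, 1]: {auc}")
    if auc <= 0.5:
        return "no_power"
    if auc < 0.7:
        return "poor"
    if auc <= 0.9:
        return "useful"
    return "highly_accurate"


def evaluate_predictions(
    probs: Sequence[float],
    labels: Sequence[int],
    threshold: float | None = None,
    train_prevalence: float | None = None,
) -> EvaluationResult:
    """Full test-split evaluation: AUC, optimal threshold, se/spe, band.

    When `threshold` is omitted it is optimised on these predictions
    (the held-out data), matching the validation protocol.
    """
    auc = roc_auc(probs, labels)
    t = optimal_threshold(probs, labels) if threshold is None else threshold
    res = confusion_stats(probs, labels, t, train_prevalence)
    res.auc = auc
    res.accuracy_band = accuracy_band(auc)
    return res


def null_replicates(
    dataset,
    habitat: str,
    fraction: float,
    n_reps: int = 10,
    base_seed: int = 0,
    terms: Sequence[str] | None = None,
    selection_mode: str = "fixed",
) -> NullSummary:
    """Random-subset ("null") models, replicated, summarised as mean and SD.

    Each replicate trains on a uniform random `fraction` of points (seed
    `base_seed + rep`) and is evaluated on the remainder; D2, AUC,
    sensitivity and specificity are averaged over replicates. Replicates
    whose training split lacks a class are excluded and counted.

    `selection_mode="fixed"` fits the supplied `terms` (the usual mode:
    terms pre-selected once on the full dataset); `"per_sample"` reruns
    AIC subset selection inside every replicate.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    if terms is None:
        from .hdm_fit import DEFAULT_TERMS
        terms = DEFAULT_TERMS
    y = dataset.habitat(habitat)
    rows = {"d2": [], "auc": [], "sensitivity": [], "specificity": []}
    n_degen = 0
    for rep in range(n_reps):
        split = random_split(dataset.n, fraction, base_seed + rep)
        tr = np.asarray(sorted(split.train))
        te = np.asarray(sorted(split.test))
        y_tr, y_te = y[tr], y[te]
        try:
            df_tr = dataset.df.iloc[tr]
            if selection_mode == "per_sample":
                fit = select_model_aic(terms, df_tr, y_tr, habitat=habitat)
            else:
                fit = fit_logistic(build_design(df_tr, terms), y_tr, habitat=habitat)
            probs = predict_prob(fit, dataset.df.iloc[te])
            ev = evaluate_predictions(probs, y_te, train_prevalence=fit.train_prevalence)
        except (DegenerateSampleError, ValueError):
            n_degen += 1
            continue
        rows["d2"].append(fit.d2)
        rows["auc"].append(ev.auc)
        rows["sensitivity"].append(ev.sensitivity)
        rows["specificity"].append(ev.specificity)
    if not rows["auc"]:
        raise DegenerateSampleError("all null replicates degenerate")
    mean = {k: float(np.mean(v)) for k, v in rows.items()}
    sd = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in rows.items()}
    return NullSummary(mean=mean, sd=sd, n_reps=n_reps, n_degenerate=n_degen)
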