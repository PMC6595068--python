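"""Experimental protocol: stratified 5-fold CV, AUC with
influence-function confidence intervals, Youden cutoffs, and
cumulative AUC-by-timeline-length curves.

Folds are stratified on the last-HF-event label; each fold's training
set donates a 10% stratified validation split (epoch selection for the
neural families, hyperparameter selection for LR).  Evaluation always
scores the *last HF event* per patient.

The cross-validated AUC confidence interval pools per-observation
influence functions computed within each test fold (the
cross-validated-AUC estimator of the LeDell-style approach); a
percentile bootstrap is available as an independent check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .encoding import (class_weights, encode_cohort, fit_schema)
from .models import ModelConfig, ReadmissionModel

logger = logging.getLogger(__name__)


class SingleClassError(ValueError):
    """A metric that needs both outcome classes saw only one."""


@dataclass
class FoldPlan:
    """Index sets for k-fold CV with nested validation splits.

    ``folds`` is a list of (train_idx, valid_idx, test_idx) tuples
    over the cohort; test sets partition the patients.
    """

    folds: list
    seed: int
    n: int

    @property
    def k(self):
        return len(self.folds)


def make_folds(labels, seed: int, k: int = 5,
               valid_frac: float = 0.1) -> FoldPlan:
    """Stratified k-fold plan over last-HF-event labels.

    Deterministic given ``seed``.  Retries with perturbed seeds (up to
    10) if any split misses a class; per-fold positive rates stay
    within 1% of the global rate.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if n < 50:
        raise ValueError("need at least 50 patients for a 5-fold plan")
    if len(np.unique(labels)) < 2:
        raise SingleClassError("both classes required for stratification")
    global_rate = labels.mean()
    last_err = None
    for attempt in range(10):
        try:
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=seed + attempt)
            folds = []
            for tr, te in skf.split(np.zeros(n), labels):
                if len(np.unique(labels[te])) < 2:
                    raise SingleClassError("test fold lost a class")
                tr2, va = train_test_split(
                    tr, test_size=valid_frac, stratify=labels[tr],
                    random_state=seed + attempt)
                if len(np.unique(labels[tr2])) < 2 \
                        or len(np.unique(labels[va])) < 2:
                    raise SingleClassError("nested split lost a class")
                if abs(labels[te].mean() - global_rate) > 0.01 + 1.0 / len(te):
                    raise SingleClassError("stratification drifted")
                folds.append((np.sort(tr2), np.sort(va), np.sort(te)))
            return FoldPlan(folds=folds, seed=seed, n=n)
        except SingleClassError as err:            # reshuffle and retry
            last_err = err
    raise SingleClassError(f"could not stratify after 10 attempts: "
                           f"{last_err}")


def auc(scores, labels) -> float:
    """Area under the ROC curve = normalized Mann-Whitney U (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("AUC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def _auc_influence(scores, labels, theta) -> np.ndarray:
    """Per-observation influence-function values for the AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    p1, p0 = n1 / len(y), n0 / len(y)
    # F0(s) = P(S0 < s) + 0.5 P(S0 = s); S1(s) = P(S1 > s) + 0.5 ties
    sneg = np.sort(neg)
    spos = np.sort(pos)
    f0 = (np.searchsorted(sneg, s, side="left")
          + 0.5 * (np.searchsorted(sneg, s, side="right")
                   - np.searchsorted(sneg, s, side="left"))) / n0
    s1 = (n1 - np.searchsorted(spos, s, side="right")
          + 0.5 * (np.searchsorted(spos, s, side="right")
                   - np.searchsorted(spos, s, side="left"))) / n1
    ic = np.where(y == 1, (f0 - theta) / p1, (s1 - theta) / p0)
    return ic


def cv_auc_ci(fold_scores, fold_labels, level: float = 0.95):
    """Cross-validated AUC with an influence-function interval.

    Returns ``(cv_auc, lo, hi)``: the mean of per-fold AUCs with a
    normal-approximation interval whose variance averages each fold's
    mean squared influence value.  Degenerate (zero) variance is
    floored to keep the interval well defined.
    """
    if len(fold_scores) < 2:
        raise ValueError("need at least 2 folds")
    aucs, icsq, n = [], [], 0
    for s, y in zip(fold_scores, fold_labels):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise SingleClassError("a fold contains a single class")
        a = auc(s, y)
        aucs.append(a)
        ic = _auc_influence(s, y, a)
        icsq.append(float((ic ** 2).mean()))
        n += len(y)
    cvauc = float(np.mean(aucs))
    sighat2 = max(float(np.mean(icsq)), 1e-300)
    se = np.sqrt(sighat2 / n)
    z = norm.ppf(0.5 + level / 2)
    return cvauc, max(cvauc - z * se, 0.0), min(cvauc + z * se, 1.0)


def bootstrap_auc_ci(scores, labels, n_boot: int = 2000, seed: int = 0,
                     level: float = 0.95):
    """Percentile-bootstrap AUC interval (independent check on
    :func:`cv_auc_ci`)."""
    rng = np.random.default_rng(seed)
    s = np.asarray(scores)
    y = np.asarray(labels)
    n = len(y)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if len(np.unique(y[idx])) < 2:
            continue
        vals.append(roc_auc_score(y[idx], s[idx]))
    lo, hi = np.percentile(vals, [100 * (0.5 - level / 2),
                                  100 * (0.5 + level / 2)])
    return float(np.mean(vals)), float(lo), float(hi)


def youden_cutoff(scores, labels):
    """Cutoff maximizing sensitivity + specificity - 1.

    Ties go to the smallest cutoff; for perfectly separated scores
    this returns the smallest observed score above all negatives.
    Reported on the probability scale of the scores.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("Youden cutoff needs both classes")
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    best = j.max()
    # roc_curve thresholds are decreasing; last maximizer = smallest
    idx = np.flatnonzero(j >= best - 1e-12)[-1]
    cutoff = float(min(thr[idx], np.max(scores)))
    return cutoff, float(tpr[idx]), float(1.0 - fpr[idx])


def auc_by_timeline_length(scores, labels, lengths,
                           cumulative: bool = True) -> pd.DataFrame:
    """AUC over patients with timeline length <= L (or == L).

    Bins containing a single class are skipped with a log note.  The
    cumulative curve at the maximum length equals the overall AUC.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    lengths = np.asarray(lengths)
    rows = []
    for L in np.unique(lengths):
        mask = lengths <= L if cumulative else lengths == L
        sub_y = labels[mask]
        if len(np.unique(sub_y)) < 2:
            logger.info("timeline-length bin L=%s has a single class; "
                        "skipped", L)
            continue
        rows.append({"length": int(L), "n": int(mask.sum()),
                     "auc": auc(scores[mask], sub_y)})
    return pd.DataFrame(rows, columns=["length", "n", "auc"])


@dataclass
class EvalReport:
    """Cross-validated evaluation of one model family."""

    family: str
    fold_aucs: list
    cv_auc: float
    ci_low: float
    ci_high: float
    youden_mean: float
    youden_sd: float
    auc_by_length: pd.DataFrame
    scores: pd.DataFrame                # patient_id, fold, score, label

    def to_dict(self) -> dict:
        return {"family": self.family,
                "fold_aucs": [float(a) for a in self.fold_aucs],
                "cv_auc": float(self.cv_auc),
                "ci_low": float(self.ci_low),
                "ci_high": float(self.ci_high),
                "youden_mean": float(self.youden_mean),
                "youden_sd": float(self.youden_sd),
                "auc_by_length": self.auc_by_length.to_dict("records")}


def evaluate_model_cv(timelines, config: ModelConfig, plan: FoldPlan,
                      summary_features: bool = False,
                      t_max: int = None) -> EvalReport:
    """Train and score one model family across all folds.

    Per fold: the feature schema and class weights are fitted on the
    training split only, the model trains with the nested validation
    split for epoch selection, and scores are produced for the test
    patients' last HF events.
    """
    labels_all = np.array([tl.last_label for tl in timelines])
    fold_scores, fold_labels, cutoffs = [], [], []
    score_rows = []
    for fold_id, (tr, va, te) in enumerate(plan.folds):
        train_tl = [timelines[i] for i in tr]
        schema = fit_schema(train_tl, summary_features=summary_features)
        enc = {name: encode_cohort([timelines[i] for i in idx], schema,
                                   t_max)
               for name, idx in (("train", tr), ("valid", va),
                                 ("test", te))}
        cw = class_weights([s.last_label for s in enc["train"]])
        res = ReadmissionModel(config).fit(enc["train"], enc["valid"],
                                           class_weight=cw)
        p = res.predict_proba(enc["test"])
        y = labels_all[te]
        fold_scores.append(p)
        fold_labels.append(y)
        cutoffs.append(youden_cutoff(p, y)[0])
        for i, pi, yi in zip(te, p, y):
            score_rows.append({"patient_id": timelines[i].patient_id,
                               "fold": fold_id, "score": float(pi),
                               "label": int(yi),
                               "length": len(timelines[i])})
    cvauc, lo, hi = cv_auc_ci(fold_scores, fold_labels)
    scores_df = pd.DataFrame(score_rows)
    curve = auc_by_timeline_length(scores_df["score"], scores_df["label"],
                                   scores_df["length"])
    return EvalReport(
        family=config.family,
        fold_aucs=[auc(s, y) for s, y in zip(fold_scores, fold_labels)],
        cv_auc=cvauc, ci_low=lo, ci_high=hi,
        youden_mean=float(np.mean(cutoffs)),
        youden_sd=float(np.std(cutoffs, ddof=1)) if len(cutoffs) > 1
        else 0.0,
        auc_by_length=curve, scores=scores_df)
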