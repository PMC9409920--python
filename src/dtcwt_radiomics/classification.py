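"""Exhaustive feature-subset evaluation with a cross-validated linear SVM.

Every nonempty subset of a (screened) feature group is evaluated with a
stratified k-fold cross-validated linear SVM (regularization ``c``, default 1,
five folds): per fold, features are standardized by training-fold mean/sd, the
SVM is fit on the training folds and the held-out fold's classes and signed
decision scores are recorded.  Metrics are computed once on the pooled
out-of-fold predictions:

* ACC/SEN/SPC/F1 from the pooled confusion counts (sensitivity and
  specificity are positive-class quantities),
* AUC as the Mann-Whitney probability with half credit for ties,
* Wilson score intervals for the proportions and a stratified percentile
  bootstrap for the AUC.

The search ranks subsets by (1) accuracy, (2) AUC, (3) smaller size,
(4) enumeration order, using one fixed fold assignment per search so that
subset comparisons share a common partition.  Because the winner is chosen on
the same pooled out-of-fold predictions it reports, searched-best metrics
carry an optimism bias; the test suite measures this on label-free noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigurationError, InputError

SUBSET_ENUMERATION_CAP = 25  # 2^25-1 subsets; larger groups need max_subset_size


@dataclass(frozen=True)
class ModelConfig:
    """SVM / cross-validation / confidence-interval settings."""

    c: float = 1.0
    k_folds: int = 5
    seed: int = 0
    positive_class: int = 1
    max_subset_size: Optional[int] = None
    bootstrap_reps: int = 2000
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ConfigurationError("c must be > 0")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigurationError("ci_level must be in (0, 1)")


# ---------------------------------------------------------------------------
# folds


def stratified_folds(labels: Sequence[int], k_folds: int, seed: int) -> np.ndarray:
    """Per-class round-robin fold assignment after a seeded shuffle.

    Within each class, members are shuffled then dealt round-robin; each
    class's starting fold is offset by the remainders already dealt, so total
    fold sizes also differ by at most one (e.g. 27+24 at k=5 gives totals
    11,10,10,10,10 with 5-6 positives per fold).
    """
    y = np.asarray(labels)
    if y.ndim != 1:
        raise InputError("labels must be a 1D vector")
    if k_folds > y.size:
        raise InputError("more folds than patients")
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        # leave-one-out (k == N) is allowed as a degenerate case; otherwise
        # every class must reach every fold
        if idx.size < k_folds and k_folds < y.size:
            raise InputError(f"class {cls} has fewer members ({idx.size}) than folds")
        perm = rng.permutation(idx)
        folds[perm] = (np.arange(perm.size) + offset) % k_folds
        offset = (offset + perm.size) % k_folds
    return folds


# ---------------------------------------------------------------------------
# metrics


def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> Dict[str, float]:
    """ACC/SEN/SPC/F1 as fractions; zero denominators give 0 with a flag."""
    n = tp + fp + tn + fn
    if n < 1:
        raise InputError("empty confusion")
    out = {"acc": (tp + tn) / n}
    flags = []
    for name, num, den in [
        ("sen", tp, tp + fn),
        ("spc", tn, tn + fp),
        ("f1", 2 * tp, 2 * tp + fp + fn),
    ]:
        if den == 0:
            out[name] = 0.0
            flags.append(name)
        else:
            out[name] = num / den
    out["undefined"] = flags
    return out


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[int]) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie) over all positive/negative pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y != 1]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes required for AUC")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def wilson_ci(successes: int, n: int, ci_level: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not (0 <= successes <= n) or n < 1:
        raise InputError("need 0 <= successes <= n, n >= 1")
    lo, hi = proportion_confint(successes, n, alpha=1 - ci_level, method="wilson")
    # the Wilson bounds are exactly 0/1 at the boundaries; strip float fuzz
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return float(lo), float(hi)


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    bootstrap_reps: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> Tuple[float, float]:
    """Stratified percentile bootstrap interval for the Mann-Whitney AUC."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y != 1]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes required for AUC")
    rng = np.random.default_rng(seed)
    aucs = np.empty(bootstrap_reps)
    ones = np.ones(pos.size, dtype=int)
    zeros = np.zeros(neg.size, dtype=int)
    yy = np.concatenate([ones, zeros])
    for r in range(bootstrap_reps):
        bp = pos[rng.integers(0, pos.size, pos.size)]
        bn = neg[rng.integers(0, neg.size, neg.size)]
        aucs[r] = auc_mann_whitney(np.concatenate([bp, bn]), yy)
    tail = (1 - ci_level) / 2
    return float(np.quantile(aucs, tail)), float(np.quantile(aucs, 1 - tail))


# ---------------------------------------------------------------------------
# subset enumeration


def enumerate_subsets(
    features: Sequence[str], max_subset_size: Optional[int] = None
) -> Iterator[Tuple[str, ...]]:
    """All nonempty subsets in size-then-lexicographic (input) order."""
    feats = list(features)
    n = len(feats)
    if n < 1:
        raise InputError("empty feature group")
    if n > SUBSET_ENUMERATION_CAP and max_subset_size is None:
        raise ConfigurationError(
            f"{n} features exceed the enumeration cap ({SUBSET_ENUMERATION_CAP}); "
            "set max_subset_size"
        )
    top = n if max_subset_size is None else min(n, max_subset_size)
    for size in range(1, top + 1):
        yield from combinations(feats, size)


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationResult:
    """Pooled out-of-fold performance of one feature subset."""

    subset: Tuple[str, ...]
    predictions: pd.DataFrame  # index = patient position; label, fold, pred, score
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spc: float
    f1: float
    auc: float
    ci: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    seed: int = 0
    evaluation_count: int = 1
    undefined_metrics: List[str] = field(default_factory=list)

    def metrics_percent(self) -> Dict[str, float]:
        return {k: round(100 * getattr(self, k), 2) for k in ("acc", "sen", "spc", "auc", "f1")}

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset),
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "metrics_percent": self.metrics_percent(),
            "ci": {k: [round(lo, 4), round(hi, 4)] for k, (lo, hi) in self.ci.items()},
            "seed": self.seed,
            "evaluation_count": self.evaluation_count,
        }


def _standardize_fold(X: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Standardize all rows by training-row mean/sd; constant features -> 0."""
    mu = X[train].mean(axis=0)
    sd = X[train].std(axis=0)
    const = sd == 0.0
    if const.any():
        warnings.warn("constant feature in training fold standardized to 0")
        sd = np.where(const, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, const] = 0.0
    return Z


class ExhaustiveSubsetSVC(ClassifierMixin, BaseEstimator):
    """Linear SVM with exhaustive subset selection by pooled out-of-fold CV.

    ``fit(X, y)`` enumerates every nonempty feature subset (size, then input
    order), evaluates each with stratified k-fold cross-validation under one
    fixed fold assignment, keeps the best by (accuracy, AUC, smaller size,
    enumeration order), and refits a final linear SVM on all rows restricted
    to the winning subset (standardized by whole-sample mean/sd).

    Parameters mirror :class:`ModelConfig`.  Fitted attributes:

    * ``best_subset_`` : winning column indices
    * ``best_result_`` : :class:`EvaluationResult` of the winner (with CIs)
    * ``evaluation_count_`` : number of subsets evaluated
    * ``cv_results_`` : per-subset (subset, acc, auc) triples if ``keep_ranking``
    """

    def __init__(
        self,
        c: float = 1.0,
        k_folds: int = 5,
        seed: int = 0,
        max_subset_size: Optional[int] = None,
        bootstrap_reps: int = 2000,
        ci_level: float = 0.95,
        keep_ranking: bool = False,
    ):
        self.c = c
        self.k_folds = k_folds
        self.seed = seed
        self.max_subset_size = max_subset_size
        self.bootstrap_reps = bootstrap_reps
        self.ci_level = ci_level
        self.keep_ranking = keep_ranking

    # -- internal ----------------------------------------------------------

    def _evaluate(self, Z_folds, y, folds, cols) -> Tuple[np.ndarray, np.ndarray]:
        """Pooled out-of-fold predictions/scores for one column subset."""
        pred = np.empty(y.size, dtype=int)
        score = np.empty(y.size, dtype=float)
        for k, Z in enumerate(Z_folds):
            test = folds == k
            train = ~test
            clf = SVC(kernel="linear", C=self.c)
            clf.fit(Z[np.ix_(train, cols)], y[train])
            sub = Z[np.ix_(test, cols)]
            pred[test] = clf.predict(sub)
            score[test] = clf.decision_function(sub)
        return pred, score

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise InputError("binary classification only")
        y01 = (y == classes[1]).astype(int)
        folds = stratified_folds(y01, self.k_folds, self.seed)
        # pre-standardize once per fold: per-feature training-fold mean/sd
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Z_folds = [_standardize_fold(X, folds != k) for k in range(self.k_folds)]

        n_feat = X.shape[1]
        best = None
        ranking = []
        count = 0
        for order, subset in enumerate(enumerate_subsets(list(range(n_feat)), self.max_subset_size)):
            cols = list(subset)
            pred, score = self._evaluate(Z_folds, y01, folds, cols)
            acc = float(np.mean(pred == y01))
            auc = auc_mann_whitney(score, y01)
            count += 1
            key = (acc, auc, -len(cols), -order)
            if best is None or key > best[0]:
                best = (key, subset, pred, score)
            if self.keep_ranking:
                ranking.append((subset, acc, auc))

        _, subset, pred, score = best
        self.classes_ = classes
        self.best_subset_ = tuple(subset)
        self.evaluation_count_ = count
        self.cv_results_ = ranking if self.keep_ranking else None
        self.folds_ = folds
        self.best_result_ = _build_result(
            subset=tuple(str(i) for i in subset),
            y=y01,
            folds=folds,
            pred=pred,
            score=score,
            seed=self.seed,
            evaluation_count=count,
            bootstrap_reps=self.bootstrap_reps,
            ci_level=self.ci_level,
        )
        # final refit on all rows for predict()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Z = _standardize_fold(X, np.ones(y01.size, dtype=bool))
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd == 0, 1.0, sd)
        self._final = SVC(kernel="linear", C=self.c)
        self._final.fit(Z[:, list(self.best_subset_)], y)
        return self

    def predict(self, X):
        check_is_fitted(self, "best_subset_")
        X = np.asarray(X, dtype=float)
        Z = (X - self._mu) / self._sd
        return self._final.predict(Z[:, list(self.best_subset_)])

    def decision_function(self, X):
        check_is_fitted(self, "best_subset_")
        X = np.asarray(X, dtype=float)
        Z = (X - self._mu) / self._sd
        return self._final.decision_function(Z[:, list(self.best_subset_)])


def _build_result(
    subset, y, folds, pred, score, seed, evaluation_count, bootstrap_reps,
    ci_level, compute_ci: bool = True,
) -> EvaluationResult:
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    m = classification_metrics(tp, fp, tn, fn)
    auc = auc_mann_whitney(score, y)
    n = y.size
    npos = int(np.sum(y == 1))
    nneg = n - npos
    ci = {}
    if compute_ci:
        ci = {
            "acc": wilson_ci(tp + tn, n, ci_level),
            "sen": wilson_ci(tp, npos, ci_level),
            "spc": wilson_ci(tn, nneg, ci_level),
            "auc": bootstrap_auc_ci(score, y, bootstrap_reps, seed, ci_level),
        }
    predictions = pd.DataFrame({"label": y, "fold": folds, "pred": pred, "score": score})
    return EvaluationResult(
        subset=tuple(subset),
        predictions=predictions,
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=m["acc"], sen=m["sen"], spc=m["spc"], f1=m["f1"], auc=auc,
        ci=ci, seed=seed, evaluation_count=evaluation_count,
        undefined_metrics=m["undefined"],
    )


# ---------------------------------------------------------------------------
# table-level wrappers


def evaluate_subset(
    table: pd.DataFrame,
    subset: Sequence[str],
    config: ModelConfig = ModelConfig(),
    folds: Optional[np.ndarray] = None,
    compute_ci: bool = True,
) -> EvaluationResult:
    """Cross-validated evaluation of one named feature subset of a table."""
    subset = list(subset)
    if not subset:
        raise InputError("empty subset")
    X = table[subset].to_numpy(dtype=float)
    y = (table["label"].to_numpy(dtype=int) == config.positive_class).astype(int)
    if folds is None:
        folds = stratified_folds(y, config.k_folds, config.seed)
    pred = np.empty(y.size, dtype=int)
    score = np.empty(y.size, dtype=float)
    for k in range(config.k_folds):
        test = folds == k
        train = ~test
        Z = _standardize_fold(X, train)
        clf = SVC(kernel="linear", C=config.c)
        clf.fit(Z[train], y[train])
        pred[test] = clf.predict(Z[test])
        score[test] = clf.decision_function(Z[test])
    return _build_result(
        subset=tuple(subset), y=y, folds=folds, pred=pred, score=score,
        seed=config.seed, evaluation_count=1,
        bootstrap_reps=config.bootstrap_reps, ci_level=config.ci_level,
        compute_ci=compute_ci,
    )


def exhaustive_search(
    table: pd.DataFrame,
    group: Sequence[str],
    config: ModelConfig = ModelConfig(),
    keep_ranking: bool = False,
) -> EvaluationResult:
    """Best subset of ``group`` by exhaustive cross-validated search.

    One fixed fold assignment (from ``config.seed``) is shared by every
    subset evaluation; the winner is re-evaluated with confidence intervals.
    """
    group = list(group)
    if not group:
        raise InputError("empty feature group")
    X = table[group].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    est = ExhaustiveSubsetSVC(
        c=config.c, k_folds=config.k_folds, seed=config.seed,
        max_subset_size=config.max_subset_size,
        bootstrap_reps=config.bootstrap_reps, ci_level=config.ci_level,
        keep_ranking=keep_ranking,
    ).fit(X, (y == config.positive_class).astype(int))
    result = est.best_result_
    named = tuple(group[i] for i in est.best_subset_)
    result.subset = named
    if keep_ranking:
        result.ranking = [
            (tuple(group[i] for i in s), acc, auc) for s, acc, auc in est.cv_results_
        ]
    return result
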