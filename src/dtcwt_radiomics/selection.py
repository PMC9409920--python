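"""Per-feature two-sample t-test screening at p < alpha.

Each feature column is compared between the two classes with a pooled-variance
Student t-test (two-sided; Welch available behind a switch).  Features with
p strictly below ``alpha`` (default 0.001) survive, grouped by transform
family (PRE / DWT / DTCWT).  No multiple-testing correction is applied - the
screen reproduces a raw-p threshold protocol and is not a statistical
endorsement of it.

Features with zero pooled variance are degenerate for the test; they are
assigned p = 1 and flagged rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .errors import DegenerateDataError, InputError
from .features import FeatureName

TRANSFORM_GROUPS = ("PRE", "DWT", "DTCWT")


def two_sample_t(values_a, values_b, equal_var: bool = True) -> Tuple[float, float]:
    """Two-sample t statistic and two-sided p-value.

    Pooled-variance Student test by default (``equal_var=False`` gives Welch).
    Raises :class:`DegenerateDataError` when the pooled variance is zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0.0:
        raise DegenerateDataError("zero pooled variance")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


class TTestFeatureSelector(SelectorMixin, BaseEstimator):
    """Feature screen keeping columns with two-sample t-test p < ``alpha``.

    scikit-learn style selector: ``fit(X, y)`` with binary ``y`` computes the
    per-feature statistics, ``transform`` keeps the surviving columns.

    Parameters
    ----------
    alpha : significance level; strict inequality ``p < alpha``.
    equal_var : pooled-variance Student test if True (default), Welch if False.

    Attributes
    ----------
    t_, pvalues_ : per-feature statistic and two-sided p-value.
    degenerate_ : boolean flags for zero-pooled-variance features (p set to 1).
    """

    def __init__(self, alpha: float = 0.001, equal_var: bool = True):
        self.alpha = alpha
        self.equal_var = equal_var

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size != 2:
            raise InputError(f"need exactly 2 classes, got {classes.size}")
        # positive class is the larger label (1 for 0/1 labels)
        pos, neg = X[y == classes[1]], X[y == classes[0]]
        if pos.shape[0] < 2 or neg.shape[0] < 2:
            raise InputError("each class needs at least 2 patients")
        import warnings

        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            # constant columns trigger scipy's precision-loss warning; they are
            # detected and flagged as degenerate below
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = sps.ttest_ind(pos, neg, axis=0, equal_var=self.equal_var)
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        degenerate = ~np.isfinite(t)
        t[degenerate] = 0.0
        p[degenerate] = 1.0
        self.t_ = t
        self.pvalues_ = p
        self.degenerate_ = degenerate
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "pvalues_")
        return self.pvalues_ < self.alpha


@dataclass
class SelectionResult:
    """Per-feature screening statistics and the surviving feature set."""

    stats: pd.DataFrame  # index = feature name; columns t, p, selected, degenerate, group
    alpha: float

    @property
    def selected(self) -> List[str]:
        return list(self.stats.index[self.stats["selected"]])

    @property
    def groups(self) -> Dict[str, List[str]]:
        """Partition of the selected features by transform family."""
        sel = self.stats[self.stats["selected"]]
        return {
            g: list(sel.index[sel["group"] == g]) for g in TRANSFORM_GROUPS
        }

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_features": int(len(self.stats)),
            "n_selected": int(self.stats["selected"].sum()),
            "groups": self.groups,
        }


def select_features(table: pd.DataFrame, alpha: float = 0.001,
                    equal_var: bool = True) -> SelectionResult:
    """Screen every feature column of a feature table.

    ``table`` is a patients x features frame with a ``label`` column
    (1 = positive class).  Deterministic given the table.
    """
    names = [c for c in table.columns if c != "label"]
    X = table[names].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    selector = TTestFeatureSelector(alpha=alpha, equal_var=equal_var).fit(X, y)
    stats = pd.DataFrame(
        {
            "t": selector.t_,
            "p": selector.pvalues_,
            "selected": selector.pvalues_ < alpha,
            "degenerate": selector.degenerate_,
            "group": [FeatureName.parse(n).transform for n in names],
        },
        index=pd.Index(names, name="feature"),
    )
    return SelectionResult(stats=stats, alpha=alpha)
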