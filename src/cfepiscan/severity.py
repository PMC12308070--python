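"""Gradient-boosted disease-probability score and clinical correlation.

A gradient boosting machine is trained on the variance-stabilized counts at
called differential regions to output a per-sample probability of SCZ in
[0, 1].  Hyperparameters are chosen by repeated stratified 3-fold
cross-validated log-loss over a small grid; the reported scores are
out-of-fold predictions so no sample is scored by a model that saw its
label.  Scores are then correlated (Spearman) with symptom severity
(PANSS-like, expected positive) and cognition (BACS-like, expected
negative).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import log_loss
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

__all__ = ["SeverityScorer", "fit_boosted_score", "correlate_severity"]

DEFAULT_GRID = tuple(
    {"n_estimators": t, "max_depth": d, "learning_rate": 0.1}
    for t in (50, 100, 200)
    for d in (1, 2, 3)
)


class SeverityScorer(BaseEstimator):
    """Out-of-fold GBM disease-probability scorer.

    Fitted attributes: ``best_params_``, ``cv_logloss_`` per grid point,
    ``scores_`` out-of-fold probabilities aligned to the input rows,
    ``folds_`` the final fold assignment.
    """

    def __init__(self, folds=3, repeats=10, grid=DEFAULT_GRID, random_state=0):
        self.folds = folds
        self.repeats = repeats
        self.grid = grid
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("need exactly two classes")
        y01 = (y == classes[1]).astype(int)
        rng_seed = self.random_state
        cv = RepeatedStratifiedKFold(
            n_splits=self.folds, n_repeats=self.repeats, random_state=rng_seed
        )
        losses = []
        for params in self.grid:
            fold_losses = []
            for tr, te in cv.split(X, y01):
                clf = GradientBoostingClassifier(random_state=rng_seed, **params)
                clf.fit(X[tr], y01[tr])
                fold_losses.append(log_loss(y01[te], clf.predict_proba(X[te])[:, 1], labels=[0, 1]))
            losses.append(float(np.mean(fold_losses)))
        best = int(np.argmin(losses))
        self.cv_logloss_ = dict(zip(map(str, self.grid), losses))
        self.best_params_ = dict(self.grid[best])

        final_cv = StratifiedKFold(n_splits=self.folds, shuffle=True, random_state=rng_seed)
        scores = np.full(len(y01), np.nan)
        folds = np.full(len(y01), -1)
        for f, (tr, te) in enumerate(final_cv.split(X, y01)):
            clf = GradientBoostingClassifier(random_state=rng_seed, **self.best_params_)
            clf.fit(X[tr], y01[tr])
            scores[te] = clf.predict_proba(X[te])[:, 1]
            folds[te] = f
        self.scores_ = scores
        self.folds_ = folds
        self.classes_ = classes
        return self


def fit_boosted_score(features, labels, folds=3, repeats=10, grid=DEFAULT_GRID, seed=0):
    """Out-of-fold disease-probability scores; thin wrapper over SeverityScorer.

    ``features``: samples x regions (e.g. VST counts at called regions);
    ``labels``: group per sample ("HC"/"SCZ").  Returns a DataFrame with
    score and fold per sample plus the fitted scorer.
    """
    scorer = SeverityScorer(folds=folds, repeats=repeats, grid=grid, random_state=seed)
    scorer.fit(features, labels)
    idx = features.index if hasattr(features, "index") else pd.RangeIndex(len(labels))
    table = pd.DataFrame({"score": scorer.scores_, "fold": scorer.folds_}, index=idx)
    return table, scorer


def correlate_severity(scores, clinical):
    """Spearman rho and two-sided p of the disease score against each
    clinical scale (columns of ``clinical``), on shared non-missing samples."""
    scores = pd.Series(scores)
    out = {}
    for col in clinical.columns:
        paired = pd.concat([scores, clinical[col]], axis=1, join="inner").dropna()
        if len(paired) < 3:
            raise ValueError(f"fewer than 3 paired values for {col!r}")
        r = stats.spearmanr(paired.iloc[:, 0], paired.iloc[:, 1])
        out[col] = {"rho": float(r.statistic), "pvalue": float(r.pvalue), "n": len(paired)}
    return out
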