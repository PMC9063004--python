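"""Internal validation: bootstrapped two-feature logistic regression.

The protocol mirrors small-cohort radiomics practice: over ``n_iter``
iterations (1,000 by default) a training subset of two-thirds of the
patients is drawn, a logistic regression with intercept on the two selected
(standardized) delta features is fit by maximum likelihood, every patient —
including the training subset — is scored, and the ROC AUC of that scoring
is recorded. The AUC distribution is summarized by its mean and empirical
2.5/97.5 percentiles. Scoring the training patients makes the summary
optimistic by construction; it is an internal consistency measure, not an
estimate of out-of-sample performance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .delta import DeltaFeatureTable
from .selection import POSITIVE_LABEL

log = logging.getLogger(__name__)

DEFAULT_N_ITER = 1000
DEFAULT_TRAIN_FRACTION = 2.0 / 3.0


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC in the Mann-Whitney form.

    The fraction of (positive, negative) pairs whose scores are correctly
    ordered, with ties counted 1/2 — computed from mid-ranks.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are required to compute an AUC")
    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class ValidationReport:
    """Bootstrap AUC summary for one dose bin and feature pair."""

    bin_tag: str
    features: List[str]
    aucs: np.ndarray
    n_iter: int
    train_fraction: float
    seed: int
    n_redrawn: int = 0
    n_ridge_refits: int = 0

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def percentile_2_5(self) -> float:
        return float(np.percentile(self.aucs, 2.5))

    @property
    def percentile_97_5(self) -> float:
        return float(np.percentile(self.aucs, 97.5))

    def summary(self) -> dict:
        return {
            "bin": self.bin_tag,
            "features": list(self.features),
            "mean_auc": self.mean_auc,
            "percentile_2.5": self.percentile_2_5,
            "percentile_97.5": self.percentile_97_5,
            "n_iter": self.n_iter,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
            "n_redrawn": self.n_redrawn,
            "n_ridge_refits": self.n_ridge_refits,
        }


def _fit_logistic(X_train: np.ndarray, y_train: np.ndarray):
    """Unpenalized ML fit; on non-convergence (separation) fall back to ridge."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
            model.fit(X_train, y_train)
            return model, False
        except ConvergenceWarning:
            pass
    model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=500)
    model.fit(X_train, y_train)
    return model, True


def bootstrap_validate(
    table: DeltaFeatureTable,
    features: Sequence[str],
    n_iter: int = DEFAULT_N_ITER,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    with_replacement: bool = False,
    standardize: bool = True,
) -> ValidationReport:
    """Bootstrap AUC distribution of a two-feature logistic model.

    Per iteration: draw ``round(train_fraction * n)`` patients (without
    replacement by default; ``with_replacement`` gives the classical
    bootstrap), standardize covariates on the training subset, fit, score
    all patients, record the AUC. Single-class training draws are redrawn
    (counted); separated fits fall back to a ridge-stabilized refit
    (counted). Percentiles use linear interpolation on the empirical
    distribution.
    """
    clean = table.dropna()
    missing = [f for f in features if f not in clean.data.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    X_all = clean.data.sort_index()[list(features)].to_numpy()
    y_all = (clean.labels.loc[clean.data.sort_index().index] == POSITIVE_LABEL).to_numpy().astype(int)
    n = len(y_all)
    if y_all.sum() in (0, n):
        raise ValueError("both response classes are required")
    n_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_iter)
    n_redrawn = 0
    n_ridge = 0
    for it in range(n_iter):
        while True:
            idx = (
                rng.choice(n, size=n_train, replace=True)
                if with_replacement
                else rng.choice(n, size=n_train, replace=False)
            )
            y_tr = y_all[idx]
            if 0 < y_tr.sum() < len(y_tr):
                break
            n_redrawn += 1
        X_tr = X_all[idx]
        if standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0)
            sd[sd == 0] = 1.0
            X_fit = (X_tr - mu) / sd
            X_score = (X_all - mu) / sd
        else:
            X_fit, X_score = X_tr, X_all
        model, ridged = _fit_logistic(X_fit, y_tr)
        n_ridge += ridged
        scores = model.predict_proba(X_score)[:, 1]
        aucs[it] = compute_auc(scores, y_all)
    if n_redrawn:
        log.info("%d single-class training draws redrawn", n_redrawn)
    if n_ridge:
        log.info("%d separated fits ridge-stabilized", n_ridge)
    return ValidationReport(
        bin_tag=table.bin_tag,
        features=list(features),
        aucs=aucs,
        n_iter=n_iter,
        train_fraction=train_fraction,
        seed=seed,
        n_redrawn=n_redrawn,
        n_ridge_refits=n_ridge,
    )
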