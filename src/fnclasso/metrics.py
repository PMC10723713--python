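"""Held-out evaluation of a fitted PRS: predictive R^2, AIC, model size.

Predictive R^2 is the squared Pearson correlation between the held-out
phenotype and the fitted values of the evaluation regression (phenotype on
genetic score, covariates and an intercept); without covariates this is the
squared correlation between score and phenotype, invariant to affine
transformations of the score. The Akaike information criterion is

    AIC = 2 q + n_test * log(RSS / n_test)        (natural log),

with q the number of SNPs in the PRS model and RSS the residual sum of
squares of the same evaluation regression, so AIC and R^2 are computed from
a single set of residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import TargetData
from .exceptions import InvalidInputError, LeakageError
from .joint_model import FittedPRS, compute_prs

__all__ = ["EvalReport", "predictive_r2", "aic", "evaluate"]


@dataclass(frozen=True)
class EvalReport:
    """Evaluation of one PRS model on one held-out sample."""

    r2: float
    aic: float
    q: int
    n_test: int
    rss: float
    method: str = ""

    def __post_init__(self):
        # internal consistency: the AIC must decompose exactly
        expected = 2 * self.q + self.n_test * math.log(self.rss / self.n_test)
        if not math.isclose(self.aic, expected, rel_tol=1e-12, abs_tol=1e-9):
            raise InvalidInputError("AIC inconsistent with (q, n_test, rss)")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "r2": float(self.r2),
            "aic": float(self.aic),
            "q": int(self.q),
            "n_test": int(self.n_test),
            "rss": float(self.rss),
        }


def _fit_eval_regression(scores, y, covariates):
    """OLS of y on [1, score, covariates]; returns fitted values."""
    cols = [np.ones(len(y))]
    if np.ptp(scores) > 0:
        cols.append(scores)
    if covariates is not None:
        cols.append(np.asarray(covariates, dtype=float).reshape(len(y), -1))
    D = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(D, y, rcond=None)
    return D @ coef


def predictive_r2(scores, y_test, covariates=None) -> float:
    """Outcome variation explained by the PRS on the testing set.

    Squared Pearson correlation between `y_test` and the fitted values of
    the regression of `y_test` on (score, covariates, intercept). Returns
    0 with a warning when the score or the phenotype has zero variance.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y_test, dtype=float).ravel()
    if scores.size != y.size:
        raise InvalidInputError("scores and y_test lengths differ")
    if y.size < 3:
        raise InvalidInputError("need at least 3 test samples")
    if np.ptp(y) == 0 or (np.ptp(scores) == 0 and covariates is None):
        warnings.warn("zero-variance score or phenotype: R^2 set to 0")
        return 0.0
    fitted = _fit_eval_regression(scores, y, covariates)
    if np.ptp(fitted) == 0:
        warnings.warn("constant fitted values: R^2 set to 0")
        return 0.0
    r = np.corrcoef(fitted, y)[0, 1]
    return float(r * r)


def aic(q: int, n_test: int, rss: float) -> float:
    """Akaike information criterion 2q + n_test * log(RSS / n_test)."""
    if n_test < 1:
        raise InvalidInputError("n_test must be >= 1")
    if q < 0:
        raise InvalidInputError("q must be non-negative")
    if not rss > 0:
        raise InvalidInputError("rss must be strictly positive")
    return 2.0 * q + n_test * math.log(rss / n_test)


def evaluate(model: FittedPRS, test: TargetData) -> EvalReport:
    """Score a fitted PRS on a held-out target sample.

    Raises
    ------
    LeakageError
        If any test sample id appears among the model's training ids.
    """
    if test.y is None:
        raise InvalidInputError("test data carries no phenotype")
    train_ids = set(model.provenance.get("train_sample_ids", ()))
    overlap = train_ids.intersection(test.sample_ids)
    if overlap:
        raise LeakageError(
            f"{len(overlap)} test samples were used for training"
        )
    scores = compute_prs(model, test)
    y = test.y
    fitted = _fit_eval_regression(scores, y, test.covariates)
    resid = y - fitted
    rss = float(resid @ resid)
    r2 = predictive_r2(scores, y, test.covariates)
    return EvalReport(
        r2=r2,
        aic=aic(model.q, test.n, rss),
        q=model.q,
        n_test=test.n,
        rss=rss,
        method=model.method,
    )
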