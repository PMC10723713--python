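"""Joint PRS model training on the target sample (FNC+Lasso steps 2-3).

For each reduced SNP set produced by FNC screening, a Lasso regression of
the phenotype on the corresponding genotype columns is fit on the target
training sample; the regularization strength is chosen by K-fold
cross-validation. Candidates are compared by their cross-validated R^2 —
in-sample R^2 is monotone in set size and would always favor the largest
set, whereas CV R^2 lets the data pick the screening level. The winner's
effect estimates beta* define the polygenic score

    PRS_i = sum_j X_ij * beta*_j (+ intercept).

Genotype columns are standardized (mean 0, variance 1) before fitting and
the coefficients are mapped back to the original dosage scale. Covariates,
when present, enter unpenalized: they are projected out of the phenotype by
ordinary least squares before the Lasso stage and reported separately from
the genetic score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV, LogisticRegressionCV
from sklearn.model_selection import KFold, StratifiedKFold

from .containers import SummaryStats, TargetData
from .exceptions import (
    AlignmentError,
    DegenerateFitError,
    InvalidInputError,
)
from .screening import default_eps_grid, fnc_screen
from .signal_estimation import SignalCountEstimate

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateFit",
    "FittedPRS",
    "fit_candidate",
    "select_model",
    "fnc_lasso",
    "compute_prs",
]


@dataclass
class CandidateFit:
    """One penalized joint fit on a reduced SNP set."""

    snp_set: tuple
    beta: np.ndarray  # original dosage scale, aligned to snp_set
    intercept: float
    selection_r2: float
    penalty: float
    eps_level: float | None = None
    covariate_effects: np.ndarray | None = None
    family: str = "gaussian"
    n_train: int = 0
    train_sample_ids: tuple = ()

    @property
    def q(self) -> int:
        return int(np.count_nonzero(self.beta))

    @property
    def support(self) -> tuple:
        return tuple(s for s, b in zip(self.snp_set, self.beta) if b != 0.0)


@dataclass
class FittedPRS:
    """The selected final PRS model (winner over the screening grid)."""

    snp_ids: tuple
    beta: np.ndarray
    intercept: float
    eps_level: float | None
    penalty: float
    selection_r2: float
    q: int
    family: str = "gaussian"
    method: str = "fnc_lasso"
    covariate_effects: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def support(self) -> tuple:
        return tuple(s for s, b in zip(self.snp_ids, self.beta) if b != 0.0)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "family": self.family,
            "eps_level": self.eps_level,
            "penalty": float(self.penalty),
            "selection_r2": float(self.selection_r2),
            "q": int(self.q),
            "intercept": float(self.intercept),
            "snps": [
                {"snp_id": s, "beta": float(b)}
                for s, b in zip(self.snp_ids, self.beta)
            ],
            "covariate_effects": (
                None
                if self.covariate_effects is None
                else [float(v) for v in self.covariate_effects]
            ),
            "provenance": {
                k: v
                for k, v in self.provenance.items()
                if k != "train_sample_ids"
            },
        }

    @classmethod
    def from_candidate(cls, c: CandidateFit, method: str, provenance=None):
        prov = dict(provenance or {})
        prov.setdefault("train_sample_ids", c.train_sample_ids)
        return cls(
            snp_ids=c.snp_set,
            beta=c.beta.copy(),
            intercept=c.intercept,
            eps_level=c.eps_level,
            penalty=c.penalty,
            selection_r2=c.selection_r2,
            q=c.q,
            family=c.family,
            method=method,
            covariate_effects=c.covariate_effects,
            provenance=prov,
        )


def _residualize(y: np.ndarray, covariates: np.ndarray | None):
    """Project covariates (plus intercept) out of y by OLS."""
    if covariates is None:
        return y, 0.0, None
    C = np.column_stack([np.ones(len(y)), covariates])
    gamma, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ gamma, float(gamma[0]), gamma[1:].copy()


def fit_candidate(
    data: TargetData,
    family: str = "gaussian",
    cv_folds: int = 10,
    seed: int = 0,
    eps_level: float | None = None,
) -> CandidateFit:
    """Fit one cross-validated Lasso on the SNP columns of `data`.

    Parameters
    ----------
    data : TargetData
        Training sample already restricted to the candidate SNP set;
        must carry a phenotype.
    family : {"gaussian", "binomial"}
        Linear model with squared loss, or L1-penalized logistic.
    cv_folds : int
        Folds for the regularization-path cross-validation (>= 2).
    seed : int
        Controls the fold assignment; identical inputs and seed give an
        identical fit.

    Returns
    -------
    CandidateFit
        Effects on the original dosage scale; ``selection_r2`` is the
        cross-validated R^2 at the chosen penalty (mean CV score for the
        binomial family).
    """
    if data.m == 0:
        raise InvalidInputError("candidate SNP set is empty")
    if data.y is None:
        raise InvalidInputError("target data carries no phenotype")
    if cv_folds < 2 or data.n < cv_folds:
        raise InvalidInputError("need n_train >= cv_folds >= 2")
    y = data.y
    if np.ptp(y) == 0:
        raise DegenerateFitError("phenotype is constant")

    mu = data.X.mean(axis=0)
    sd = data.X.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Xs = (data.X - mu) / sd_safe

    rs = int(seed) % (2**31)
    if family == "gaussian":
        y_work, cov_intercept, cov_effects = _residualize(y, data.covariates)
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=rs)
        # glmnet-style path: 100 alphas down to 0.01*alpha_max (n < p
        # convention); Gram precomputation speeds up repeated CV fits.
        las = LassoCV(cv=cv, alphas=100, eps=1e-2, max_iter=2000, tol=1e-4,
                      precompute=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            las.fit(Xs, y_work)
        mean_mse = las.mse_path_.mean(axis=1)
        best = int(np.argmin(mean_mse))
        var_y = float(np.var(y_work))
        selection_r2 = 1.0 - float(mean_mse[best]) / var_y if var_y > 0 else 0.0
        beta = las.coef_ / sd_safe
        intercept = float(las.intercept_) - float(mu @ beta) + cov_intercept
        penalty = float(las.alpha_)
    elif family == "binomial":
        classes = np.unique(y)
        if classes.size != 2:
            raise DegenerateFitError("binomial family needs a binary phenotype")
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rs)
        X_fit = Xs
        cov_effects = None
        cov_intercept = 0.0
        if data.covariates is not None:
            X_fit = np.column_stack([Xs, data.covariates])
        lr = LogisticRegressionCV(
            Cs=10, cv=cv, penalty="l1", solver="saga",
            scoring="neg_log_loss", max_iter=5000, random_state=rs,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            lr.fit(X_fit, (y == classes.max()).astype(int))
        coef = lr.coef_.ravel()
        beta = coef[: data.m] / sd_safe
        if data.covariates is not None:
            cov_effects = coef[data.m:].copy()
        intercept = float(lr.intercept_[0]) - float(mu @ beta)
        penalty = float(1.0 / lr.C_[0])
        selection_r2 = float(np.max(lr.scores_[1].mean(axis=0)))
    else:
        raise InvalidInputError(f"unknown family: {family!r}")

    beta = np.where(sd == 0, 0.0, beta)
    return CandidateFit(
        snp_set=data.snp_ids,
        beta=beta,
        intercept=intercept,
        selection_r2=selection_r2,
        penalty=penalty,
        eps_level=eps_level,
        covariate_effects=cov_effects,
        family=family,
        n_train=data.n,
        train_sample_ids=data.sample_ids,
    )


def select_model(
    candidates: Sequence[CandidateFit],
    method: str = "fnc_lasso",
    provenance: dict | None = None,
) -> FittedPRS:
    """Pick the candidate with the largest selection R^2.

    Ties are broken toward the smaller SNP set, then the smaller screening
    level, so the selection is reproducible and parsimonious.
    """
    cands = list(candidates)
    if not cands:
        raise InvalidInputError("no candidates to select from")

    def key(c: CandidateFit):
        eps = c.eps_level if c.eps_level is not None else float("inf")
        return (-c.selection_r2, len(c.snp_set), eps)

    winner = min(cands, key=key)
    prov = dict(provenance or {})
    prov["candidates"] = [
        {
            "eps": c.eps_level,
            "set_size": len(c.snp_set),
            "selection_r2": float(c.selection_r2),
            "q": c.q,
        }
        for c in cands
    ]
    return FittedPRS.from_candidate(winner, method, prov)


def fnc_lasso(
    sumstats: SummaryStats,
    data: TargetData,
    eps_grid: Sequence[float] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    family: str = "gaussian",
    s_hat: SignalCountEstimate | int | None = None,
) -> FittedPRS:
    """FNC screening on base p-values + joint Lasso re-training on target.

    Composes :func:`fnc_screen` over the eps grid, fits each distinct
    reduced SNP set once with :func:`fit_candidate` on `data` (the target
    training sample), and returns the cross-validated-R^2 winner.

    SNP ids of `sumstats` and `data` are intersected; a warning is logged
    when either side has ids the other lacks.
    """
    common = [s for s in data.snp_ids if s in set(sumstats.snp_ids)]
    if not common:
        raise AlignmentError("no overlapping SNP ids between base and target")
    if len(common) < data.m or len(common) < len(sumstats.snp_ids):
        logger.warning(
            "SNP id mismatch: %d common of %d target / %d base",
            len(common), data.m, len(sumstats.snp_ids),
        )
        data = data.restrict(common)
    pvec = sumstats.p_values(common)
    grid = default_eps_grid() if eps_grid is None else np.asarray(eps_grid, float)
    screen = fnc_screen(pvec, grid, s_hat=s_hat)

    fits: dict[int, CandidateFit] = {}
    candidates = []
    for k, eps in enumerate(screen.eps_grid):
        j = screen.cutoff_index[k]
        if j in fits:  # identical set already fit: share, keep first eps
            base = fits[j]
        else:
            base = fit_candidate(
                data.restrict(screen.reduced_sets[k]),
                family=family, cv_folds=cv_folds, seed=seed,
                eps_level=float(eps),
            )
            fits[j] = base
            candidates.append(base)
        logger.debug(
            "eps=%.3f |D|=%d cv_r2=%.4f", eps, j, base.selection_r2
        )
    prov = {
        "seed": int(seed),
        "eps_grid": [float(e) for e in screen.eps_grid],
        "s_hat": int(screen.s_hat),
        "cutoffs": [int(j) for j in screen.cutoff_index],
    }
    return select_model(candidates, method="fnc_lasso", provenance=prov)


def compute_prs(model: FittedPRS, X_new, snp_ids=None) -> np.ndarray:
    """Genetic score of each row of `X_new` under a fitted PRS model.

    Parameters
    ----------
    model : FittedPRS
    X_new : TargetData or ndarray
        New genotype dosages; when an ndarray, `snp_ids` labels columns.
    snp_ids : sequence of str, optional
        Required for plain arrays.

    Returns
    -------
    ndarray
        ``score_i = sum_j X_ij beta_j + intercept`` over the support of
        beta. Covariate effects are not included.
    """
    if isinstance(X_new, TargetData):
        X, ids = X_new.X, X_new.snp_ids
    else:
        X = np.asarray(X_new, dtype=float)
        if snp_ids is None:
            raise InvalidInputError("snp_ids required with a plain matrix")
        ids = tuple(str(s) for s in snp_ids)
    col = {s: i for i, s in enumerate(ids)}
    support = model.support
    missing = [s for s in support if s not in col]
    if missing:
        raise AlignmentError(f"genotypes lack model SNPs: {missing[:10]}")
    if not support:
        return np.full(X.shape[0], model.intercept)
    idx = [col[s] for s in support]
    b = np.array([model.beta[model.snp_ids.index(s)] for s in support])
    return X[:, idx] @ b + model.intercept
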