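"""Baseline PRS constructions: SIS+Lasso, Lasso on all SNPs, clumping+thresholding.

- SIS+Lasso ranks SNPs by their base p-values, keeps the top
  ``min(m, n_train - 1)`` (sure independence screening with the
  conventional sample-size cap), and re-trains a joint Lasso on the target
  training data — a fixed-size analogue of FNC screening.
- Lasso ignores the base data entirely and fits the penalized joint model
  on all target SNPs.
- Clumping+thresholding never re-estimates effects: correlated SNPs are
  greedily pruned using an LD reference (keeping the most significant SNP
  per clump), a p-value threshold is tuned to maximize training R^2, and
  the PRS weights are the base marginal effects of the surviving SNPs.

External published methods (lassosum, LDpred) are not reimplemented; their
scores can be supplied to the benchmark harness as precomputed tables.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .containers import SummaryStats, TargetData
from .exceptions import AlignmentError, InvalidInputError
from .joint_model import FittedPRS, fit_candidate, select_model
from .ld import LDReference

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_P_GRID",
    "sis_screen_ids",
    "sis_lasso",
    "lasso_all",
    "clump",
    "clump_threshold",
]

DEFAULT_P_GRID = (1e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)


def _common_ids(sumstats: SummaryStats, data: TargetData) -> list:
    base = set(sumstats.snp_ids)
    common = [s for s in data.snp_ids if s in base]
    if not common:
        raise AlignmentError("no overlapping SNP ids between base and target")
    return common


def sis_screen_ids(sumstats: SummaryStats, ids: Sequence[str], n_train: int) -> tuple:
    """The min(m, n_train - 1) ids with smallest base p-values.

    Ties at the cutoff are broken by SNP id (stable lexicographic order),
    so the screening set is reproducible.
    """
    if n_train < 2:
        raise InvalidInputError("n_train must be >= 2")
    pvec = sumstats.p_values(ids)
    order = np.lexsort((np.asarray(pvec.ids, dtype=object), pvec.p))
    k = min(len(ids), n_train - 1)
    return tuple(pvec.ids[i] for i in order[:k])


def sis_lasso(
    sumstats: SummaryStats,
    data: TargetData,
    cv_folds: int = 10,
    seed: int = 0,
    family: str = "gaussian",
) -> FittedPRS:
    """Sure-independence screening of base p-values + joint Lasso."""
    common = _common_ids(sumstats, data)
    keep = sis_screen_ids(sumstats, common, data.n)
    fit = fit_candidate(
        data.restrict(keep), family=family, cv_folds=cv_folds, seed=seed
    )
    return select_model(
        [fit], method="sis_lasso",
        provenance={"seed": int(seed), "screen_size": len(keep)},
    )


def lasso_all(
    data: TargetData,
    cv_folds: int = 10,
    seed: int = 0,
    family: str = "gaussian",
) -> FittedPRS:
    """Cross-validated Lasso on every target SNP (no base information)."""
    fit = fit_candidate(data, family=family, cv_folds=cv_folds, seed=seed)
    return select_model([fit], method="lasso", provenance={"seed": int(seed)})


def clump(
    sumstats: SummaryStats,
    ld: LDReference,
    ids: Sequence[str],
    r2_thresh: float = 0.1,
    window_kb: float = 250.0,
) -> tuple:
    """Greedy LD clumping: iterate SNPs by ascending p-value; each surviving
    SNP becomes an index SNP and removes SNPs within `window_kb` whose
    squared correlation with it exceeds `r2_thresh`.

    SNPs absent from the LD reference are treated as unlinked (warning).
    Returns the surviving ids in ascending-p order.
    """
    pvec = sumstats.p_values(ids)
    order = np.lexsort((np.asarray(pvec.ids, dtype=object), pvec.p))
    ordered = [pvec.ids[i] for i in order]
    pos = {s: ld.positions[ld._index[s]] for s in ordered if s in ld._index}
    unknown = [s for s in ordered if s not in pos]
    if unknown:
        logger.warning(
            "%d SNPs missing from LD reference, treated as unlinked", len(unknown)
        )
    removed: set = set()
    survivors = []
    window = window_kb * 1000.0
    for s in ordered:
        if s in removed:
            continue
        survivors.append(s)
        if s not in pos:
            continue
        ps = pos[s]
        for t in ordered:
            if t == s or t in removed or t not in pos:
                continue
            if abs(pos[t] - ps) <= window:
                r2 = ld.r2(s, t)
                if r2 is not None and r2 > r2_thresh:
                    removed.add(t)
    return tuple(survivors)


def clump_threshold(
    sumstats: SummaryStats,
    ld: LDReference,
    data: TargetData,
    r2_thresh: float = 0.1,
    window_kb: float = 250.0,
    p_grid: Sequence[float] = DEFAULT_P_GRID,
    seed: int = 0,
) -> FittedPRS:
    """Clumping + p-value thresholding with base marginal effect weights.

    For each threshold in `p_grid`, the PRS uses the base effects of the
    clumped SNPs with p-value at or below the threshold; the threshold
    maximizing R^2 of the training phenotype regressed on the PRS (with
    intercept) wins, ties going to the smaller threshold. Effects are never
    re-estimated, matching the classical C+T construction.
    """
    if "effect" not in sumstats.table.columns:
        raise InvalidInputError("clump_threshold needs an effect column")
    if data.y is None:
        raise InvalidInputError("target data carries no phenotype")
    common = _common_ids(sumstats, data)
    survivors = clump(sumstats, ld, common, r2_thresh, window_kb)
    tab = sumstats.table.set_index("snp_id")
    p = tab.loc[list(survivors), "p"].to_numpy(float)
    eff = tab.loc[list(survivors), "effect"].to_numpy(float)
    Xs = data.restrict(survivors).X
    y = data.y

    best = None
    for thr in sorted(p_grid):
        mask = p <= thr
        if not mask.any():
            continue
        score = Xs[:, mask] @ eff[mask]
        if np.ptp(score) == 0 or np.ptp(y) == 0:
            r2 = 0.0
        else:
            r = np.corrcoef(score, y)[0, 1]
            r2 = float(r * r)
        if best is None or r2 > best[0] + 1e-15:
            best = (r2, thr, mask)
    if best is None:
        raise InvalidInputError("no SNP passes any threshold in p_grid")
    r2, thr, mask = best
    kept = tuple(s for s, k in zip(survivors, mask) if k)
    beta = eff[mask]
    return FittedPRS(
        snp_ids=kept,
        beta=beta,
        intercept=0.0,
        eps_level=None,
        penalty=float(thr),
        selection_r2=r2,
        q=int(mask.sum()),
        method="clump_threshold",
        provenance={
            "seed": int(seed),
            "r2_thresh": float(r2_thresh),
            "window_kb": float(window_kb),
            "p_threshold": float(thr),
            "n_clumped": len(survivors),
            "train_sample_ids": data.sample_ids,
        },
    )
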