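"""False-negative-control (FNC) marginal screening.

Given base-data p-values sorted increasingly, p_(1) <= ... <= p_(m), and an
estimate ``s_hat`` of the number of signal variants, the estimated false
negative proportion when keeping only the top j SNPs is

    FNP_hat(j) = max( 1 - j/s_hat + (m - s_hat) p_(j) / s_hat , 0 ).

Rationale: of the top j SNPs roughly ``(m - s_hat) p_(j)`` are nulls (the
expected false-positive count at threshold p_(j)), so the true-positive
count is about ``j - (m - s_hat) p_(j)`` and the missed-signal fraction is
one minus that over s_hat. For a tolerated level eps the adaptive cutoff is
the first index where the estimated curve drops strictly below eps,

    j*(eps) = min{ j : FNP_hat(j) < eps },

and the reduced SNP set D(eps) is the j*(eps) smallest-p SNPs. Because the
true FNP is non-increasing in j, stopping at the first crossing yields the
smallest set whose FNP is controlled at eps with high probability. Running
a grid eps_1 < ... < eps_K gives nested candidate sets D_K ⊆ ... ⊆ D_1 for
joint-model training.

Conventions (fixed here so results are reproducible across platforms):
ties in p are broken by SNP id via a stable lexicographic sort; p = 0
underflow is accepted as the smallest rank without flooring; when no index
crosses below eps the cutoff falls back to j* = m (keep everything — the
conservative continuation); the estimated curve is clamped below at 0 but
may exceed 1 for small j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateSignalError, InvalidInputError
from .signal_estimation import (
    PValueVector,
    SignalCountEstimate,
    estimate_signal_count,
)

__all__ = [
    "FNPCurve",
    "ScreeningResult",
    "default_eps_grid",
    "fnp_curve",
    "threshold_index",
    "fnc_screen",
]

#: sentinel returned by threshold_index when no index qualifies
ALL = "all"


def default_eps_grid() -> np.ndarray:
    """The default FNP control-level grid {0.02, 0.04, ..., 0.40} (K=20)."""
    return np.round(np.arange(1, 21) * 0.02, 10)


@dataclass(frozen=True)
class FNPCurve:
    """Estimated FNP as a function of the number of retained SNPs.

    ``fnp_hat[j-1]`` is the estimate when the j SNPs with smallest p-values
    are kept; ``sorted_ids`` lists SNP ids in increasing p-value order
    (ties broken by id).
    """

    fnp_hat: np.ndarray
    sorted_ids: tuple
    sorted_p: np.ndarray
    s_hat: int

    def __len__(self) -> int:
        return self.fnp_hat.size


@dataclass(frozen=True)
class ScreeningResult:
    """Reduced SNP sets over a grid of FNP control levels.

    ``reduced_sets[k]`` is the ordered id list D_k for ``eps_grid[k]``;
    ``cutoff_index[k]`` is j*_k = |D_k|. Sets are nested decreasingly in
    eps. ``duplicate_of[k]`` points at the first earlier level with an
    identical set (or -1), so training can fit each distinct set once.
    """

    eps_grid: np.ndarray
    cutoff_index: tuple
    reduced_sets: tuple
    s_hat: int
    duplicate_of: tuple = field(default=(), compare=False)

    def to_dict(self) -> dict:
        """JSON-serializable summary."""
        return {
            "s_hat": int(self.s_hat),
            "levels": [
                {
                    "eps": float(e),
                    "cutoff_index": int(j),
                    "snp_ids": list(ids),
                }
                for e, j, ids in zip(
                    self.eps_grid, self.cutoff_index, self.reduced_sets
                )
            ],
        }


def _sort_by_p(p: PValueVector):
    """Stable order by (p, id) — the package-wide tie-break rule."""
    order = np.lexsort((np.asarray(p.ids, dtype=object), p.p))
    return order


def fnp_curve(p: PValueVector, s_hat: SignalCountEstimate | int) -> FNPCurve:
    """Evaluate the estimated FNP curve at every cutoff j = 1..m."""
    if not isinstance(p, PValueVector):
        p = PValueVector(p)
    s = s_hat.s_hat if isinstance(s_hat, SignalCountEstimate) else int(s_hat)
    if s <= 0:
        raise DegenerateSignalError(
            "s_hat = 0: no signals estimated, screening is meaningless"
        )
    m = len(p)
    if s > m:
        raise InvalidInputError("s_hat cannot exceed the number of SNPs")
    order = _sort_by_p(p)
    sorted_p = p.p[order]
    j = np.arange(1, m + 1)
    fnp = np.maximum(1.0 - j / s + (m - s) * sorted_p / s, 0.0)
    return FNPCurve(
        fnp_hat=fnp,
        sorted_ids=tuple(p.ids[i] for i in order),
        sorted_p=sorted_p,
        s_hat=s,
    )


def threshold_index(curve: FNPCurve, eps: float):
    """Smallest j with FNP_hat(j) strictly below eps, or the sentinel "all".

    Raises
    ------
    InvalidInputError
        If eps is outside the open interval (0, 1).
    """
    if not 0.0 < eps < 1.0:
        raise InvalidInputError("eps must lie strictly in (0, 1)")
    below = np.flatnonzero(curve.fnp_hat < eps)
    if below.size == 0:
        return ALL
    return int(below[0] + 1)


def fnc_screen(
    p: PValueVector | Sequence[float],
    eps_grid: Sequence[float] | None = None,
    s_hat: SignalCountEstimate | int | None = None,
) -> ScreeningResult:
    """Run FNC screening over a grid of control levels.

    Parameters
    ----------
    p : PValueVector or array-like
        Base-data marginal p-values.
    eps_grid : increasing sequence in (0, 1), optional
        FNP control levels; defaults to {0.02, 0.04, ..., 0.40}.
    s_hat : SignalCountEstimate or int, optional
        Signal-count estimate; computed from `p` with the default
        estimator when absent.

    Returns
    -------
    ScreeningResult
        One reduced set per level, nested decreasingly in eps.
    """
    if not isinstance(p, PValueVector):
        p = PValueVector(p)
    grid = default_eps_grid() if eps_grid is None else np.asarray(eps_grid, float)
    if grid.ndim != 1 or grid.size == 0:
        raise InvalidInputError("eps_grid must be a non-empty 1-D sequence")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise InvalidInputError("eps levels must lie strictly in (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise InvalidInputError("eps_grid must be strictly increasing")
    if s_hat is None:
        s_hat = estimate_signal_count(p)
    curve = fnp_curve(p, s_hat)  # raises DegenerateSignalError on s_hat = 0

    m = len(p)
    cutoffs, sets, dup = [], [], []
    seen: dict[int, int] = {}
    for k, eps in enumerate(grid):
        j = threshold_index(curve, float(eps))
        j = m if j == ALL else j
        cutoffs.append(j)
        sets.append(tuple(curve.sorted_ids[:j]))
        if j in seen:
            dup.append(seen[j])
        else:
            seen[j] = k
            dup.append(-1)
    # nesting is structural (prefixes of one sorted list) — assert anyway
    assert all(a >= b for a, b in zip(cutoffs, cutoffs[1:])), "nesting violated"
    s_val = s_hat.s_hat if isinstance(s_hat, SignalCountEstimate) else int(s_hat)
    return ScreeningResult(
        eps_grid=grid,
        cutoff_index=tuple(cutoffs),
        reduced_sets=tuple(sets),
        s_hat=s_val,
        duplicate_of=tuple(dup),
    )
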