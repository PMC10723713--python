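"""Core in-memory containers: base summary statistics and target data.

``SummaryStats`` wraps a per-SNP table of marginal GWAS results from the
base cohort (id, alleles, effect, p-value) plus the base sample size n0.
``TargetData`` holds the individual-level target cohort: a genotype dosage
matrix X (n samples x m SNPs), the phenotype y, and optional unpenalized
covariates (principal components, sex, age...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InvalidInputError
from .signal_estimation import PValueVector

__all__ = ["SummaryStats", "TargetData"]


@dataclass
class SummaryStats:
    """Per-SNP marginal statistics from the base GWAS.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns: ``snp_id`` (unique), ``p`` in [0,1]; optionally ``effect``
        (marginal effect or z), ``se``, ``effect_allele``, ``other_allele``.
    n0 : float
        Base-data sample size (> 0).
    provenance : dict
        Source file and column mapping, for audit.
    """

    table: pd.DataFrame
    n0: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.table
        if "snp_id" not in t.columns or "p" not in t.columns:
            raise InvalidInputError("summary table needs snp_id and p columns")
        if t["snp_id"].duplicated().any():
            raise InvalidInputError("duplicate snp_id in summary table")
        p = t["p"].to_numpy(dtype=float)
        if len(t) and (np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1):
            raise InvalidInputError("p-values must lie in [0, 1]")
        if len(t) == 0:
            raise InvalidInputError("summary table is empty")
        if not self.n0 > 0:
            raise InvalidInputError("n0 must be positive")
        self.table = t.reset_index(drop=True)

    @property
    def snp_ids(self) -> tuple:
        return tuple(self.table["snp_id"].astype(str))

    def p_values(self, ids=None) -> PValueVector:
        """P-values as a PValueVector, optionally restricted/ordered by ids."""
        t = self.table
        if ids is not None:
            sub = t.set_index("snp_id").reindex(list(ids))
            if sub["p"].isna().any():
                missing = [i for i, v in zip(ids, sub["p"].isna()) if v]
                raise AlignmentError(f"ids missing from summary stats: {missing[:5]}")
            return PValueVector(sub["p"].to_numpy(float), ids)
        return PValueVector(t["p"].to_numpy(float), self.snp_ids)

    def restrict(self, ids) -> "SummaryStats":
        """Subset (and reorder) to the given SNP ids."""
        sub = self.table.set_index("snp_id").reindex(list(ids)).reset_index()
        if sub["p"].isna().any():
            raise AlignmentError("some requested ids absent from summary stats")
        return SummaryStats(sub, self.n0, dict(self.provenance))


@dataclass
class TargetData:
    """Individual-level target cohort.

    Attributes
    ----------
    X : ndarray, shape (n, m)
        Genotype dosages (0..2) or standardized reals; no missing values.
    y : ndarray, shape (n,), optional
        Phenotype (continuous or 0/1).
    snp_ids : tuple of str
        Column identifiers, unique, aligned to X.
    covariates : ndarray, shape (n, c), optional
        Unpenalized covariates.
    sample_ids : tuple of str
        Row identifiers; generated when absent.
    """

    X: np.ndarray
    y: np.ndarray | None = None
    snp_ids: tuple = ()
    covariates: np.ndarray | None = None
    sample_ids: tuple = ()
    covariate_names: tuple = ()
    alleles: dict | None = None  # snp_id -> (effect/A1, other/A2), if known

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InvalidInputError("X must be 2-D (samples x SNPs)")
        n, m = self.X.shape
        if np.any(~np.isfinite(self.X)):
            raise InvalidInputError("X contains missing/non-finite values")
        if not self.snp_ids:
            self.snp_ids = tuple(f"snp{i}" for i in range(m))
        else:
            self.snp_ids = tuple(str(s) for s in self.snp_ids)
        if len(self.snp_ids) != m or len(set(self.snp_ids)) != m:
            raise InvalidInputError("snp_ids must be unique and match X columns")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float).ravel()
            if self.y.size != n:
                raise InvalidInputError("y length must match X rows")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise InvalidInputError("covariate rows must match X rows")
        if not self.sample_ids:
            self.sample_ids = tuple(f"s{i}" for i in range(n))
        else:
            self.sample_ids = tuple(str(s) for s in self.sample_ids)
        if len(self.sample_ids) != n:
            raise InvalidInputError("sample_ids length must match X rows")
        self._col = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def restrict(self, ids) -> "TargetData":
        """Subset columns to the given SNP ids (order preserved from ids)."""
        try:
            cols = [self._col[str(s)] for s in ids]
        except KeyError as e:
            raise AlignmentError(f"SNP id not present in target data: {e}") from e
        return TargetData(
            self.X[:, cols], self.y, tuple(str(s) for s in ids),
            self.covariates, self.sample_ids, self.covariate_names,
            self.alleles,
        )

    def take_rows(self, idx) -> "TargetData":
        idx = np.asarray(idx, dtype=int)
        return TargetData(
            self.X[idx],
            None if self.y is None else self.y[idx],
            self.snp_ids,
            None if self.covariates is None else self.covariates[idx],
            tuple(self.sample_ids[i] for i in idx),
            self.covariate_names,
            self.alleles,
        )

    def split(self, seed: int | np.random.Generator = 0):
        """Random 1:1 split into (train, test), reproducible from `seed`."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perm = rng.permutation(self.n)
        half = self.n // 2
        return self.take_rows(np.sort(perm[:half])), self.take_rows(np.sort(perm[half:]))
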