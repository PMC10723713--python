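"""Linkage-disequilibrium correlation models.

The simulation engine and the clumping+thresholding baseline both need a
SNP correlation matrix Sigma. Real panels give a dense estimate; for
synthetic studies structured models are cheaper and sufficient:

- ``independent``: Sigma = I.
- ``ar1(rho)``: Sigma_ij = rho^|i-j| across the whole panel.
- ``blocks(size, rho)``: disjoint blocks of ``size`` adjacent SNPs, AR(1)
  with parameter ``rho`` inside each block, independence across blocks —
  a coarse stand-in for LD blocks separated by recombination hotspots.
- explicit dense matrix.

The structured models never materialize the m x m matrix: sampling uses the
AR(1) innovation recursion and matrix-vector products use the two-pass
AR(1) identity, both O(m) per vector.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["LDModel", "LDReference", "make_sigma"]


def _ar1_sample(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n rows i.i.d. N(0, Sigma) with Sigma_ij = rho^|i-j|, via recursion."""
    z = rng.standard_normal((n, m))
    if m == 1 or rho == 0.0:
        return z
    x = np.empty_like(z)
    x[:, 0] = z[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        x[:, j] = rho * x[:, j - 1] + c * z[:, j]
    return x


def _ar1_matvec(v: np.ndarray, rho: float) -> np.ndarray:
    """(Sigma v) for AR(1) Sigma, via forward/backward geometric passes."""
    m = v.size
    if rho == 0.0:
        return v.copy()
    fwd = np.empty(m)  # sum_{j<i} rho^(i-j) v_j
    bwd = np.empty(m)  # sum_{j>i} rho^(j-i) v_j
    acc = 0.0
    for i in range(m):
        acc = rho * acc + (rho * v[i - 1] if i else 0.0)
        fwd[i] = acc
    acc = 0.0
    for i in range(m - 1, -1, -1):
        acc = rho * (acc + (v[i + 1] if i < m - 1 else 0.0))
        bwd[i] = acc
    return v + fwd + bwd


class LDModel:
    """A SNP correlation model with O(m) sampling and matvec.

    Construct via :func:`make_sigma`.
    """

    def __init__(self, kind: str, m: int, rho: float = 0.0,
                 block_size: int = 0, matrix: np.ndarray | None = None):
        self.kind = kind
        self.m = int(m)
        self.rho = float(rho)
        self.block_size = int(block_size)
        self.matrix = matrix
        if matrix is not None:
            self._chol = np.linalg.cholesky(matrix)

    # -- block bookkeeping -------------------------------------------------
    def _blocks(self):
        if self.kind == "blocks":
            edges = list(range(0, self.m, self.block_size)) + [self.m]
            return list(zip(edges[:-1], edges[1:]))
        return [(0, self.m)]

    # -- core operations ---------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n i.i.d. rows from N(0, Sigma)."""
        if self.kind == "independent":
            return rng.standard_normal((n, self.m))
        if self.kind == "explicit":
            return rng.standard_normal((n, self.m)) @ self._chol.T
        if self.kind == "ar1":
            return _ar1_sample(rng, n, self.m, self.rho)
        out = np.empty((n, self.m))
        for lo, hi in self._blocks():
            out[:, lo:hi] = _ar1_sample(rng, n, hi - lo, self.rho)
        return out

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """Sigma @ v."""
        v = np.asarray(v, dtype=float)
        if v.shape != (self.m,):
            raise InvalidInputError("vector length must equal m")
        if self.kind == "independent":
            return v.copy()
        if self.kind == "explicit":
            return self.matrix @ v
        if self.kind == "ar1":
            return _ar1_matvec(v, self.rho)
        out = np.empty(self.m)
        for lo, hi in self._blocks():
            out[lo:hi] = _ar1_matvec(v[lo:hi], self.rho)
        return out

    def corr(self, i: int, j: int) -> float:
        """Sigma_ij."""
        if self.kind == "explicit":
            return float(self.matrix[i, j])
        if i == j:
            return 1.0
        if self.kind == "independent":
            return 0.0
        if self.kind == "ar1":
            return self.rho ** abs(i - j)
        if i // self.block_size != j // self.block_size:
            return 0.0
        return self.rho ** abs(i - j)

    def to_dense(self) -> np.ndarray:
        """Materialize Sigma (use only for small m)."""
        if self.kind == "explicit":
            return self.matrix.copy()
        idx = np.arange(self.m)
        if self.kind == "independent":
            return np.eye(self.m)
        d = np.abs(idx[:, None] - idx[None, :])
        sig = self.rho ** d
        if self.kind == "blocks":
            same = (idx[:, None] // self.block_size) == (idx[None, :] // self.block_size)
            sig = np.where(same, sig, 0.0)
        np.fill_diagonal(sig, 1.0)
        return sig


def make_sigma(sigma_spec, m: int) -> LDModel:
    """Build an :class:`LDModel` from a specification.

    Parameters
    ----------
    sigma_spec : str, tuple or ndarray
        "independent"; ("ar1", rho); ("blocks", size, rho); or an explicit
        m x m correlation matrix (symmetric, unit diagonal, PSD).
    m : int
        Number of SNPs.
    """
    if m < 1:
        raise InvalidInputError("m must be at least 1")
    if isinstance(sigma_spec, str):
        if sigma_spec == "independent":
            return LDModel("independent", m)
        raise InvalidInputError(f"unknown sigma spec: {sigma_spec!r}")
    if isinstance(sigma_spec, np.ndarray):
        s = np.asarray(sigma_spec, dtype=float)
        if s.shape != (m, m):
            raise InvalidInputError("explicit Sigma must be m x m")
        if not np.allclose(s, s.T):
            raise InvalidInputError("explicit Sigma must be symmetric")
        if not np.allclose(np.diag(s), 1.0):
            raise InvalidInputError("explicit Sigma must have unit diagonal")
        if np.linalg.eigvalsh(s).min() < -1e-8:
            raise InvalidInputError("explicit Sigma must be positive semidefinite")
        # lift tiny negative eigenvalues so Cholesky succeeds
        s = s + 1e-10 * np.eye(m)
        return LDModel("explicit", m, matrix=s)
    kind = sigma_spec[0]
    if kind == "ar1":
        rho = float(sigma_spec[1])
        if not -1 < rho < 1:
            raise InvalidInputError("ar1 rho must lie in (-1, 1)")
        return LDModel("ar1", m, rho=rho)
    if kind == "blocks":
        size, rho = int(sigma_spec[1]), float(sigma_spec[2])
        if size < 1:
            raise InvalidInputError("block size must be >= 1")
        if not -1 < rho < 1:
            raise InvalidInputError("block rho must lie in (-1, 1)")
        return LDModel("blocks", m, rho=rho, block_size=size)
    raise InvalidInputError(f"unknown sigma spec: {sigma_spec!r}")


class LDReference:
    """LD panel for clumping: pairwise correlations plus SNP positions.

    Parameters
    ----------
    model : LDModel or ndarray
        Correlation structure (dense matrices accepted directly).
    positions : array-like of int, optional
        Base-pair positions, 1-based; defaults to 1 kb spacing.
    ids : sequence of str, optional
        SNP identifiers; default snp0..snp{m-1}.
    """

    def __init__(self, model, positions=None, ids=None):
        if isinstance(model, np.ndarray):
            model = make_sigma(model, model.shape[0])
        self.model = model
        m = model.m
        if positions is None:
            positions = np.arange(1, m + 1) * 1000
        self.positions = np.asarray(positions, dtype=np.int64)
        if self.positions.shape != (m,):
            raise InvalidInputError("positions length must equal m")
        self.ids = tuple(ids) if ids is not None else tuple(
            f"snp{i}" for i in range(m)
        )
        if len(self.ids) != m:
            raise InvalidInputError("ids length must equal m")
        self._index = {s: i for i, s in enumerate(self.ids)}

    def r2(self, id_a: str, id_b: str) -> float | None:
        """Squared correlation between two SNPs; None if either is unknown."""
        ia, ib = self._index.get(id_a), self._index.get(id_b)
        if ia is None or ib is None:
            return None
        return self.model.corr(ia, ib) ** 2
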