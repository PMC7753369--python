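"""Multi-resolution singular value decomposition (MSVD).

MSVD plays the role of a wavelet filter bank with the fixed filters replaced
by data-adaptive singular vectors.  One level works on a matrix ``X`` of even
dimensions ``(2n, 2m)``:

1. *Blockify* — every non-overlapping 2x2 block of ``X`` becomes one column of
   a data matrix ``A`` of shape ``(4, n*m)``, the block's entries stacked in
   the order upper-left, upper-right, lower-left, lower-right.  Blocks are
   enumerated block-row-major.
2. *Rotate* — the full SVD ``A = U S V^T`` gives a 4x4 orthogonal ``U``; the
   scatter matrix ``T = U^T A`` has rows whose norms are the singular values.
3. *Split* — each row of ``T`` is reshaped to an ``n x m`` subband.  Row 1
   (largest singular value) is the approximation ``G1``; rows 2-4 are the
   detail subbands ``G2..G4``.

Levels recurse on the approximation, exactly as a dyadic wavelet pyramid
recurses on the low-pass branch.  Every step is an orthogonal (hence
invertible and energy-preserving) linear map, so reconstruction is exact to
rounding error.

Matrices whose dimensions are not divisible by ``2^L`` are padded by edge
replication up to the next multiple; the padding is recorded in the pyramid
and cropped on reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BlockDataMatrix",
    "MsvdLevel",
    "MsvdPyramid",
    "blockify",
    "deblockify",
    "msvd_level",
    "msvd_decompose",
    "msvd_reconstruct",
    "max_msvd_level",
]


@dataclass
class BlockDataMatrix:
    """4 x (n*m) matrix of stacked 2x2 blocks of a (2n, 2m) source."""

    A: np.ndarray
    n: int
    m: int

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (4, self.n * self.m):
            raise ValueError(f"A must be 4x{self.n * self.m}, got {self.A.shape}")


@dataclass
class MsvdLevel:
    """One MSVD level: orthogonal U, singular values, four subbands."""

    U: np.ndarray            # 4x4 orthogonal
    S: np.ndarray            # 4 singular values, descending (zero-padded)
    subbands: list           # [G1, G2, G3, G4], each n x m
    n: int
    m: int

    @property
    def approximation(self) -> np.ndarray:
        return self.subbands[0]

    @property
    def details(self) -> list:
        return self.subbands[1:]


@dataclass
class MsvdPyramid:
    """L-level MSVD pyramid.

    ``levels[l]`` decomposes the approximation of ``levels[l-1]``.  Only the
    coarsest level's approximation is needed for reconstruction (the finer
    ones are implied), mirroring the storage rule of the fusion scheme; they
    are kept on the level objects for inspection but reconstruction reads
    ``levels[-1].approximation`` plus every level's details and U.
    """

    levels: list[MsvdLevel]
    original_shape: tuple[int, int]
    pad: tuple[int, int] = (0, 0)   # rows, cols of edge padding applied

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def blockify(X: np.ndarray) -> BlockDataMatrix:
    """Rearrange a (2n, 2m) matrix into the 4 x (n*m) block data matrix.

    Column ``i*m + j`` holds block (i, j) as (UL, UR, LL, LR)^T.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("blockify expects a 2-D matrix")
    r, c = X.shape
    if r % 2 or c % 2:
        raise ValueError(f"both dimensions must be even, got {X.shape}; pad first")
    n, m = r // 2, c // 2
    # (2n, 2m) -> (n, 2, m, 2) -> (n, m, 2, 2) -> (n*m, 4) -> (4, n*m)
    blocks = X.reshape(n, 2, m, 2).transpose(0, 2, 1, 3).reshape(n * m, 4).T
    return BlockDataMatrix(blocks, n, m)


def deblockify(A, n: int, m: int) -> np.ndarray:
    """Exact inverse of :func:`blockify`."""
    mat = A.A if isinstance(A, BlockDataMatrix) else np.asarray(A, dtype=float)
    if mat.shape != (4, n * m):
        raise ValueError(f"expected shape (4, {n * m}), got {mat.shape}")
    return mat.T.reshape(n, m, 2, 2).transpose(0, 2, 1, 3).reshape(2 * n, 2 * m)


def _signfix(U: np.ndarray) -> np.ndarray:
    """Flip columns of U so each column's first nonzero entry is positive.

    Makes the decomposition deterministic across SVD backends; the flip is
    compensated implicitly because T is computed from the fixed U.
    """
    U = U.copy()
    for j in range(U.shape[1]):
        col = U[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            U[:, j] = -col
    return U


def msvd_level(X: np.ndarray) -> MsvdLevel:
    """One MSVD analysis step on an even-dimensioned matrix."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("msvd_level requires finite entries")
    bd = blockify(X)
    U, S, _ = np.linalg.svd(bd.A, full_matrices=True)
    U = _signfix(U)
    S4 = np.zeros(4)
    S4[: S.size] = S
    T = U.T @ bd.A
    subbands = [T[i].reshape(bd.n, bd.m) for i in range(4)]
    return MsvdLevel(U=U, S=S4, subbands=subbands, n=bd.n, m=bd.m)


def max_msvd_level(shape: tuple[int, int]) -> int:
    """Deepest pyramid allowed: 2^L must not exceed either original dimension."""
    lo = min(shape)
    if lo < 2:
        raise ValueError(f"matrix too small for MSVD: shape {shape}")
    return int(np.floor(np.log2(lo)))


def _pad_to_multiple(X: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    r, c = X.shape
    pr = (-r) % mult
    pc = (-c) % mult
    if pr or pc:
        X = np.pad(X, ((0, pr), (0, pc)), mode="edge")
    return X, (pr, pc)


def msvd_decompose(X: np.ndarray, L: int = 1) -> MsvdPyramid:
    """Build an L-level MSVD pyramid of ``X``.

    ``X`` is edge-padded up to dimensions divisible by ``2^L`` (padding
    recorded for exact cropping on reconstruction); level ``l+1`` decomposes
    level ``l``'s approximation subband.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("msvd_decompose expects a non-empty 2-D matrix")
    if L < 1:
        raise ValueError("L must be >= 1")
    lmax = max_msvd_level(X.shape)
    if L > lmax:
        raise ValueError(f"L={L} exceeds maximum {lmax} for shape {X.shape}")
    padded, pad = _pad_to_multiple(X, 2 ** L)
    levels = []
    cur = padded
    for _ in range(L):
        lev = msvd_level(cur)
        levels.append(lev)
        cur = lev.approximation
    return MsvdPyramid(levels=levels, original_shape=X.shape, pad=pad)


def msvd_reconstruct(p: MsvdPyramid) -> np.ndarray:
    """Invert an MSVD pyramid exactly (padding cropped)."""
    cur = p.levels[-1].approximation
    for lev in reversed(p.levels):
        if cur.shape != (lev.n, lev.m):
            raise ValueError(
                f"approximation shape {cur.shape} inconsistent with level grid "
                f"({lev.n}, {lev.m})"
            )
        rows = [cur] + [np.asarray(d) for d in lev.details]
        T = np.stack([r.reshape(lev.n * lev.m) for r in rows])
        A = lev.U @ T
        cur = deblockify(A, lev.n, lev.m)
    r, c = p.original_shape
    return cur[:r, :c]
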