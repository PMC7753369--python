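"""Feature extraction: symlet DWT filter bank and statistical descriptors.

The discrete wavelet transform is a cascade of quadrature-mirror low/high
pass filters with dyadic downsampling; the level-``i`` outputs are the
approximation ``A_i`` (low-pass branch) and detail ``D_i`` (high-pass).  The
deepest approximation of an amplitude-modulated biosignal concentrates the
slow task-related power, which is why ``A_L`` serves as the discriminative
EEG feature downstream.

The boundary convention here is *periodic*: the signal is treated as
circular, so for an orthonormal filter pair the transform is an orthonormal
change of basis and energy is conserved exactly — a property the test suite
exploits.  Symmetric extension is available via ``mode="symmetric"`` for
callers who prefer reduced wrap-around artifacts over exact energy
bookkeeping.  Filter taps come from PyWavelets; the high-pass taps are
derived from the low-pass ones by the quadrature-mirror relation
``h[k] = (-1)^k g[F-1-k]`` so the relation holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import stats as sps

from .signal_io import Epochs

__all__ = [
    "WaveletFilters",
    "DwtCoefficients",
    "dwt_step",
    "dwt_decompose",
    "max_decomposition_level",
    "stat_features",
    "STAT_FEATURE_NAMES",
    "spatial_average",
    "minmax_normalize",
]

STAT_FEATURE_NAMES = ("M", "P", "SK", "KR", "SD", "VAR")


@dataclass(frozen=True)
class WaveletFilters:
    """Quadrature-mirror decomposition filter pair.

    ``g`` is the low-pass and ``h`` the high-pass analysis filter; both have
    length ``F`` and satisfy ``h[k] = (-1)^k * g[F-1-k]``.
    """

    name: str
    g: np.ndarray
    h: np.ndarray

    @property
    def F(self) -> int:
        return len(self.g)

    @classmethod
    def from_name(cls, name: str = "sym4") -> "WaveletFilters":
        """Build the pair from any orthogonal PyWavelets wavelet name."""
        w = pywt.Wavelet(name)
        if not w.orthogonal:
            raise ValueError(f"{name!r} is not an orthogonal wavelet")
        g = np.asarray(w.dec_lo, dtype=float)
        F = len(g)
        h = np.array([(-1) ** k * g[F - 1 - k] for k in range(F)])
        return cls(name=name, g=g, h=h)


@dataclass
class DwtCoefficients:
    """All levels of a DWT: approximations A_1..A_L and details D_1..D_L."""

    approximations: list
    details: list

    @property
    def L(self) -> int:
        return len(self.approximations)

    def level(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """1-based level accessor returning (A_i, D_i)."""
        return self.approximations[i - 1], self.details[i - 1]


def _extend_even(x: np.ndarray, mode: str) -> np.ndarray:
    # periodic DWT needs an even length; odd signals get one wrapped/edge sample
    if len(x) % 2:
        extra = x[:1] if mode == "periodic" else x[-1:]
        x = np.concatenate([x, extra])
    return x


def dwt_step(x, filters: WaveletFilters | None = None, mode: str = "periodic"):
    """One analysis step: filter with (g, h) and keep every second output.

    With the periodic convention, ``A[i] = sum_k g[k] * x[(2i + k) mod N]``
    (correlation form) and likewise for ``D`` with ``h``; N must be even, odd
    signals are extended by one sample first.
    """
    if filters is None:
        filters = WaveletFilters.from_name("sym4")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("dwt_step expects a 1-D signal")
    if len(x) < filters.F:
        raise ValueError(
            f"signal length {len(x)} shorter than filter length {filters.F}"
        )
    x = _extend_even(x, mode)
    N = len(x)
    if mode == "periodic":
        idx = (np.arange(0, N, 2)[:, None] + np.arange(filters.F)[None, :]) % N
        win = x[idx]
    elif mode == "symmetric":
        ext = np.concatenate([x[::-1], x, x[::-1]])
        start = N + np.arange(0, N, 2)[:, None]
        win = ext[start + np.arange(filters.F)[None, :]]
    else:
        raise ValueError(f"unknown boundary mode {mode!r}")
    A = win @ filters.g
    D = win @ filters.h
    return A, D


def max_decomposition_level(N: int, F: int) -> int:
    """Deepest usable DWT level for signal length N and filter length F.

    floor(log2(N / (F - 1))); raises when even one level is impossible.
    """
    if N < F:
        raise ValueError(f"signal length {N} shorter than filter length {F}")
    L = int(np.floor(np.log2(N / (F - 1))))
    if L < 1:
        raise ValueError(f"signal too short for one level (N={N}, F={F})")
    return L


def dwt_decompose(x, L: int, filters: WaveletFilters | None = None,
                  mode: str = "periodic") -> DwtCoefficients:
    """Recursive DWT: level i+1 decomposes the level-i approximation."""
    if filters is None:
        filters = WaveletFilters.from_name("sym4")
    x = np.asarray(x, dtype=float)
    lmax = max_decomposition_level(len(x), filters.F)
    if L < 1 or L > lmax:
        raise ValueError(f"L={L} outside [1, {lmax}] for length {len(x)}")
    approximations, details = [], []
    cur = x
    for _ in range(L):
        A, D = dwt_step(cur, filters, mode=mode)
        approximations.append(A)
        details.append(D)
        cur = A
    return DwtCoefficients(approximations, details)


def stat_features(x, partial: bool = False) -> np.ndarray:
    """The six statistical descriptors (M, P, SK, KR, SD, VAR) of a vector.

    M = mean, P = peak (maximum value), SK = skewness and KR = raw kurtosis
    (population central moments: m3/m2^1.5, m4/m2^2), SD/VAR with the sample
    (n-1) convention.  A constant vector has no defined SK/KR: by default
    that raises; with ``partial=True`` those two entries come back NaN and
    the other four are still valid.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("stat_features expects a 1-D vector of length >= 2")
    m = float(np.mean(x))
    p = float(np.max(x))
    sd = float(np.std(x, ddof=1))
    var = float(np.var(x, ddof=1))
    m2 = float(np.var(x))  # population
    if m2 == 0.0:
        if not partial:
            raise ValueError("constant input: skewness/kurtosis undefined "
                             "(pass partial=True for the remaining features)")
        sk = kr = np.nan
    else:
        sk = float(sps.skew(x, bias=True))
        kr = float(sps.kurtosis(x, fisher=False, bias=True))
    return np.array([m, p, sk, kr, sd, var])


def spatial_average(epochs: Epochs, channels) -> np.ndarray:
    """Mean over a channel subset, per trial: (trials, samples)."""
    channels = list(channels)
    if not channels:
        raise ValueError("channel subset must be non-empty")
    sub = epochs.select_channels(channels)
    return sub.data.mean(axis=1)


def minmax_normalize(v) -> np.ndarray:
    """Rescale a vector to [0, 1]; a constant vector maps to all zeros."""
    v = np.asarray(v, dtype=float)
    lo, hi = np.min(v), np.max(v)
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)
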