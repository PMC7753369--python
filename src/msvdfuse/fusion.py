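"""MSVD fusion rules and the two end-to-end fusion schemes.

Given two signals decomposed into MSVD pyramids of identical geometry, the
per-level rules are:

* detail subbands — element-wise pick of the entry with the larger absolute
  value (the stronger local structure wins, sign preserved; exact ties go to
  the first argument, which the pipeline makes the EEG stream);
* singular-vector matrices — arithmetic mean;
* the coarsest approximation — arithmetic mean.

Reconstructing the fused pyramid yields the fused signal.  Fusing a signal
with itself is the identity: every rule returns its input, so the scheme is
consistent in the degenerate case.

Two architectures use these rules:

* **feature-based fusion** — each modality is first reduced to one 6-vector
  per trial (EEG: mean of the normalized deepest-approximation DWT vector
  per selected channel; fNIRS: the six statistical descriptors of the
  spatially averaged selected channels); the two 6-vectors are zero-padded
  to 2x4 matrices, MSVD-fused, and the cropped 6-vector is classified.
* **system-based fusion** — the two synchronized 6-channel trial matrices
  are MSVD-fused directly and features of any kind are then extracted from
  the fused signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .msvd import MsvdLevel, MsvdPyramid, msvd_decompose, msvd_reconstruct
from .signal_io import Epochs

__all__ = [
    "FusedPyramid",
    "fuse_details",
    "fuse_pyramids",
    "feature_based_fusion",
    "system_based_fusion",
]


@dataclass
class FusedPyramid(MsvdPyramid):
    """An MsvdPyramid produced by fusing two sources."""

    provenance: str = ""


def fuse_details(Da, Db) -> np.ndarray:
    """Element-wise max-absolute selection with sign preserved (tie -> Da)."""
    Da = np.asarray(Da, dtype=float)
    Db = np.asarray(Db, dtype=float)
    if Da.shape != Db.shape:
        raise ValueError(f"detail shapes differ: {Da.shape} vs {Db.shape}")
    return np.where(np.abs(Da) >= np.abs(Db), Da, Db)


def fuse_pyramids(Pa: MsvdPyramid, Pb: MsvdPyramid,
                  provenance: str = "") -> FusedPyramid:
    """Apply the fusion rules level-by-level to two congruent pyramids."""
    if Pa.n_levels != Pb.n_levels:
        raise ValueError(f"level counts differ: {Pa.n_levels} vs {Pb.n_levels}")
    if Pa.original_shape != Pb.original_shape or Pa.pad != Pb.pad:
        raise ValueError("pyramids decompose different geometries")
    fused_levels = []
    for la, lb in zip(Pa.levels, Pb.levels):
        if (la.n, la.m) != (lb.n, lb.m):
            raise ValueError("level grids differ")
        U = 0.5 * (la.U + lb.U)
        details = [fuse_details(da, db) for da, db in zip(la.details, lb.details)]
        approx = np.zeros((la.n, la.m))
        subbands = [approx] + details
        fused_levels.append(MsvdLevel(U=U, S=np.zeros(4), subbands=subbands,
                                      n=la.n, m=la.m))
    # approximation is stored only at the coarsest level, as averaged input
    top_a, top_b = Pa.levels[-1], Pb.levels[-1]
    fused_levels[-1].subbands[0] = 0.5 * (top_a.approximation + top_b.approximation)
    return FusedPyramid(levels=fused_levels, original_shape=Pa.original_shape,
                        pad=Pa.pad, provenance=provenance)


def fuse_matrices(Xa: np.ndarray, Xb: np.ndarray, L: int = 1) -> np.ndarray:
    """Decompose-fuse-reconstruct two equal-shape matrices in one call."""
    Xa = np.asarray(Xa, dtype=float)
    Xb = np.asarray(Xb, dtype=float)
    if Xa.shape != Xb.shape:
        raise ValueError(f"shapes differ: {Xa.shape} vs {Xb.shape}")
    Pa = msvd_decompose(Xa, L)
    Pb = msvd_decompose(Xb, L)
    return msvd_reconstruct(fuse_pyramids(Pa, Pb))


def _vec6_to_mat(v: np.ndarray) -> np.ndarray:
    """6-vector -> 2x4 matrix, zero-padded by two trailing entries."""
    return np.concatenate([v, np.zeros(2)]).reshape(2, 4)


def feature_based_fusion(eeg_feats: np.ndarray, nirs_feats: np.ndarray,
                         L: int = 1) -> np.ndarray:
    """Fuse per-trial 6-vectors of the two modalities (trials x 6 each).

    Each pair of 6-vectors is zero-padded into 2x4 matrices, MSVD-fused at
    depth ``L``, reconstructed, cropped back to 6 entries.  Returns a
    (trials, 6) array ready for classification.
    """
    eeg_feats = np.atleast_2d(np.asarray(eeg_feats, dtype=float))
    nirs_feats = np.atleast_2d(np.asarray(nirs_feats, dtype=float))
    if eeg_feats.shape != nirs_feats.shape:
        raise ValueError(
            f"trial/feature counts differ: {eeg_feats.shape} vs {nirs_feats.shape}"
        )
    if eeg_feats.shape[1] != 6:
        raise ValueError("feature-based fusion expects 6 features per trial")
    out = np.empty_like(eeg_feats)
    for t in range(eeg_feats.shape[0]):
        fused = fuse_matrices(_vec6_to_mat(eeg_feats[t]),
                              _vec6_to_mat(nirs_feats[t]), L=L)
        out[t] = fused.reshape(-1)[:6]
    return out


def system_based_fusion(eeg_epochs: Epochs, nirs_epochs: Epochs,
                        L: int = 1) -> Epochs:
    """Fuse synchronized trial matrices of the two modalities signal-wise.

    Both epoch sets must share (trials, channels, samples) and sampling
    rate; the fused trial matrices form a new Epochs object from which any
    feature family can be extracted.
    """
    if eeg_epochs.data.shape != nirs_epochs.data.shape:
        raise ValueError(
            "epoch grids differ "
            f"({eeg_epochs.data.shape} vs {nirs_epochs.data.shape}); "
            "synchronize both modalities onto the common grid first"
        )
    if eeg_epochs.fs != nirs_epochs.fs:
        raise ValueError("sampling rates differ; synchronize first")
    fused = np.empty_like(eeg_epochs.data)
    for t in range(eeg_epochs.n_trials):
        fused[t] = fuse_matrices(eeg_epochs.data[t], nirs_epochs.data[t], L=L)
    names = [f"fused{i + 1:02d}" for i in range(eeg_epochs.n_channels)]
    return Epochs(fused, eeg_epochs.labels.copy(), eeg_epochs.fs, names)
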