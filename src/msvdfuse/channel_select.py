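"""Correlation-based cross-modal channel selection.

Channels are ranked by the Pearson correlation between the two modalities'
filtered signals on a common grid.  Raw EEG oscillations and slow
hemodynamics are nearly uncorrelated sample-by-sample, so the EEG side is
reduced to its 1-s RMS band-power envelope before correlating (disable with
``envelope=False`` if the input is already a slow representation).

The ranking key is |rho| — neurovascular coupling can flip sign across
chromophores — and the greedy pair walk guarantees the same number of
selected channels per modality, which system-level fusion requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import Recording

__all__ = ["ChannelRanking", "pearson", "rank_channels"]


@dataclass
class ChannelRanking:
    """All cross-modal channel pairs sorted by |rho|, plus the k selected
    channels per modality."""

    pairs: list            # (eeg_name, nirs_name, rho), |rho| descending
    selected_eeg: list
    selected_nirs: list

    def to_tsv(self) -> str:
        lines = ["eeg\tnirs\trho"]
        lines += [f"{e}\t{n}\t{r:.6f}" for e, n, r in self.pairs]
        return "\n".join(lines) + "\n"


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    nx, ny = np.linalg.norm(xd), np.linalg.norm(yd)
    if nx == 0 or ny == 0:
        raise ValueError("constant input has undefined correlation")
    return float(np.clip(xd @ yd / (nx * ny), -1.0, 1.0))


def _smooth_envelope(data: np.ndarray, fs: float, window_s: float = 1.0) -> np.ndarray:
    """Per-channel sliding RMS of width ``window_s`` (same length, edge pad)."""
    w = max(int(round(window_s * fs)), 1)
    sq = data ** 2
    cs = np.cumsum(np.concatenate([np.zeros((data.shape[0], 1)), sq], axis=1), axis=1)
    sm = (cs[:, w:] - cs[:, :-w]) / w
    deficit = data.shape[1] - sm.shape[1]
    if deficit > 0:
        sm = np.pad(sm, ((0, 0), (0, deficit)), mode="edge")
    return np.sqrt(np.maximum(sm, 0.0))


def rank_channels(eeg: Recording, nirs: Recording, k: int,
                  envelope: bool = True) -> ChannelRanking:
    """Rank every EEG x NIRS channel pair by |rho| and greedily select k
    distinct channels per modality.

    Both recordings must already be on the common synchronized grid (equal
    sample counts).  Ties in |rho| break toward lower channel indices, so
    the output is deterministic and the top-k selection is nested in the
    top-(k+1) one.
    """
    if eeg.n_samples != nirs.n_samples:
        raise ValueError(
            "sample counts differ; synchronize the recordings onto a common "
            "grid (preprocess.synchronize / moving_average_downsize) first"
        )
    if not (1 <= k <= min(eeg.n_channels, nirs.n_channels)):
        raise ValueError(f"k={k} out of range for channel counts "
                         f"{eeg.n_channels}/{nirs.n_channels}")
    edata = _smooth_envelope(eeg.data, eeg.fs) if envelope else eeg.data
    rho = np.empty((eeg.n_channels, nirs.n_channels))
    for i in range(eeg.n_channels):
        for j in range(nirs.n_channels):
            rho[i, j] = pearson(edata[i], nirs.data[j])
    # sort by (-|rho|, i, j): deterministic, lower index wins ties
    order = sorted(
        ((i, j) for i in range(eeg.n_channels) for j in range(nirs.n_channels)),
        key=lambda ij: (-abs(rho[ij[0], ij[1]]), ij[0], ij[1]),
    )
    pairs = [(eeg.channel_names[i], nirs.channel_names[j], float(rho[i, j]))
             for i, j in order]
    sel_e: list[str] = []
    sel_n: list[str] = []
    for i, j in order:
        if len(sel_e) >= k and len(sel_n) >= k:
            break
        e_name, n_name = eeg.channel_names[i], nirs.channel_names[j]
        if e_name not in sel_e and n_name not in sel_n:
            if len(sel_e) < k and len(sel_n) < k:
                sel_e.append(e_name)
                sel_n.append(n_name)
    return ChannelRanking(pairs=pairs, selected_eeg=sel_e, selected_nirs=sel_n)
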