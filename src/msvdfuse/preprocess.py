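"""Signal conditioning: Butterworth filtering, the modified Beer–Lambert law,
baseline standardization, resampling, and the 1-s moving-average downsizing
that puts EEG and fNIRS on a common grid.

Two dataset presets mirror the conditioning used with public hybrid-BCI
corpora: ``buccino`` (EEG band-pass 1–50 Hz order 4 causal; HbO/HbR band-pass
0.01–0.2 Hz order 4) and ``tuberlin`` (EEG down-sampled to 200 Hz then
band-pass 1–40 Hz order 6 zero-phase; NIRS down-sampled to 10 Hz then
low-pass 0.2 Hz order 6 zero-phase).  The ``synthetic`` preset follows the
buccino parameters on the generator's native rates.

All filtering runs in second-order-section form for numerical stability at
the very low normalized corner frequencies hemodynamics requires.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable

import numpy as np
from scipy import signal as sg

from .signal_io import Modality, Recording

__all__ = [
    "FilterSpec",
    "MbllParams",
    "DEFAULT_MBLL",
    "butterworth_filter",
    "mbll",
    "baseline_standardize",
    "downsample",
    "moving_average_downsize",
    "power_envelope",
    "synchronize",
    "PRESETS",
    "apply_preset",
]


@dataclass(frozen=True)
class FilterSpec:
    """IIR Butterworth filter description.

    ``zero_phase=True`` applies forward-backward filtering (squared magnitude
    response, no phase lag, reflection padding); ``False`` is single-pass
    causal.
    """

    kind: str                  # "lowpass" | "bandpass"
    low_hz: float | None
    high_hz: float
    order: int = 4
    zero_phase: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "bandpass"):
            raise ValueError(f"kind must be lowpass or bandpass, got {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.kind == "bandpass" and (self.low_hz is None or self.low_hz >= self.high_hz):
            raise ValueError("bandpass requires 0 < low_hz < high_hz")


# Extinction coefficients for HbO/HbR at 760/850 nm in cm^-1 * mM^-1
# (order: rows = wavelengths, cols = [HbO, HbR]); values from the standard
# compiled absorption tables used throughout the fNIRS literature.
_DEFAULT_EXT = np.array([
    [1.4866, 3.8437],   # 760 nm
    [2.5264, 1.7986],   # 850 nm
])


@dataclass(frozen=True)
class MbllParams:
    """Modified Beer–Lambert parameters for a dual-wavelength optode.

    ``extinction[i, j]`` is the coefficient of chromophore j (HbO, HbR) at
    wavelength i, in cm^-1 per unit concentration; ``dpf`` are the two
    differential pathlength factors; ``distance_cm`` the source–detector
    separation.
    """

    wavelengths: tuple[float, float] = (760.0, 850.0)
    extinction: np.ndarray = None
    dpf: tuple[float, float] = (6.0, 6.0)
    distance_cm: float = 3.0

    def __post_init__(self) -> None:
        ext = self.extinction if self.extinction is not None else _DEFAULT_EXT
        ext = np.asarray(ext, dtype=float)
        if ext.shape != (2, 2):
            raise ValueError("extinction must be 2x2 (wavelengths x chromophores)")
        if abs(np.linalg.det(ext)) < 1e-12:
            raise ValueError("extinction matrix is singular")
        object.__setattr__(self, "extinction", ext)
        if self.distance_cm <= 0 or min(self.dpf) <= 0:
            raise ValueError("distance_cm and dpf must be > 0")


DEFAULT_MBLL = MbllParams()


def _design(spec: FilterSpec, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if spec.high_hz >= nyq:
        raise ValueError(f"edge {spec.high_hz} Hz >= Nyquist {nyq} Hz")
    if spec.kind == "bandpass":
        if spec.low_hz <= 0:
            raise ValueError("bandpass low edge must be > 0")
        wn = [spec.low_hz / nyq, spec.high_hz / nyq]
        btype = "bandpass"
    else:
        wn = spec.high_hz / nyq
        btype = "lowpass"
    return sg.butter(spec.order, wn, btype=btype, output="sos")


def butterworth_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Filter every channel of a recording with the given Butterworth spec."""
    sos = _design(spec, rec.fs)
    if spec.zero_phase:
        padlen = min(rec.n_samples - 1, max(3 * spec.order * 2, 3 * (2 * len(sos))))
        if rec.n_samples <= padlen:
            raise ValueError(
                f"signal of {rec.n_samples} samples too short for zero-phase padding"
            )
        out = sg.sosfiltfilt(sos, rec.data, axis=1, padlen=padlen)
    else:
        out = sg.sosfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=out)


def mbll(intensity: Recording, params: MbllParams = DEFAULT_MBLL,
         baseline_window: tuple[int, int] | None = None) -> tuple[Recording, Recording]:
    """Convert dual-wavelength optical intensity to HbO/HbR concentration
    changes via the modified Beer–Lambert law.

    Channels must be ordered in optode pairs: rows (2k, 2k+1) are the same
    optode at the two wavelengths.  Per optode, the optical-density change
    relative to the baseline-window mean is
    ``dOD_l = -log10(I_l / mean(I_l[baseline]))`` and the 2x2 system
    ``dOD_l = (eps[l, HbO] * dHbO + eps[l, HbR] * dHbR) * d * DPF_l`` is
    solved sample-wise.
    """
    if intensity.modality is not Modality.NIRS_INTENSITY:
        raise ValueError(f"mbll requires NIRS_INTENSITY input, got {intensity.modality}")
    if intensity.n_channels % 2:
        raise ValueError("channel count must be even (wavelength pairs per optode)")
    lo, hi = baseline_window if baseline_window is not None else (0, intensity.n_samples)
    if np.any(intensity.data <= 0):
        raise ValueError("optical intensities must be strictly positive")
    base = intensity.data[:, lo:hi].mean(axis=1, keepdims=True)
    dod = -np.log10(intensity.data / base)
    # pathlength-scaled system matrix, inverted once
    M = params.extinction * (params.distance_cm * np.asarray(params.dpf)[:, None])
    Minv = np.linalg.inv(M)
    n_opt = intensity.n_channels // 2
    hbo = np.empty((n_opt, intensity.n_samples))
    hbr = np.empty_like(hbo)
    for k in range(n_opt):
        conc = Minv @ dod[2 * k:2 * k + 2]
        hbo[k] = conc[0]
        hbr[k] = conc[1]
    names = [f"opt{k + 1:02d}" for k in range(n_opt)]
    mk = lambda d, mod: Recording(d, fs=intensity.fs, channel_names=list(names),
                                  modality=mod, units="mM")
    return mk(hbo, Modality.HBO), mk(hbr, Modality.HBR)


def baseline_standardize(rec: Recording) -> Recording:
    """Per-channel z-scoring: subtract the mean, divide by the population SD."""
    mu = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)  # population (divide by n)
    flat = np.flatnonzero(sd[:, 0] == 0)
    if flat.size:
        raise ValueError(
            f"constant channel(s) cannot be standardized: "
            f"{[rec.channel_names[i] for i in flat]}"
        )
    return rec.copy_with(data=(rec.data - mu) / sd)


def _ratio(target_fs: float, fs: float) -> tuple[int, int]:
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    return frac.numerator, frac.denominator


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased rational resampling to a lower rate."""
    if target_fs >= rec.fs:
        raise ValueError(f"target {target_fs} Hz must be below source {rec.fs} Hz")
    up, down = _ratio(target_fs, rec.fs)
    out = sg.resample_poly(rec.data, up, down, axis=1)
    return rec.copy_with(data=out, fs=target_fs)


def moving_average_downsize(rec: Recording, window_s: float = 1.0,
                            target_fs: float = 10.0,
                            non_overlapping: bool = False) -> Recording:
    """1-s moving-average smoothing followed by resampling onto the common
    grid, so EEG and fNIRS end up with identical per-trial sample counts.

    ``non_overlapping=True`` replaces the sliding mean + resample with block
    means of ``window_s`` (rate becomes ``1/window_s``).
    """
    w = int(round(window_s * rec.fs))
    if w < 1:
        raise ValueError("window shorter than one sample")
    if w > rec.n_samples:
        raise ValueError(f"window of {w} samples longer than signal ({rec.n_samples})")
    if non_overlapping:
        nblk = rec.n_samples // w
        out = rec.data[:, : nblk * w].reshape(rec.n_channels, nblk, w).mean(axis=2)
        return rec.copy_with(data=out, fs=rec.fs / w)
    # valid sliding mean via cumulative sums: sm[i] = mean(x[i : i + w])
    cs = np.cumsum(np.concatenate(
        [np.zeros((rec.n_channels, 1)), rec.data], axis=1), axis=1)
    sm = (cs[:, w:] - cs[:, :-w]) / w        # length N - w + 1
    n_valid = sm.shape[1]
    stride = rec.fs / target_fs
    if stride < 1:
        raise ValueError("target_fs above source rate; downsizing only")
    pos = np.arange(0, n_valid - 1e-9, stride)
    if float(stride).is_integer():
        out = sm[:, pos.astype(int)]
    else:  # slow smoothed signal: linear interpolation onto the target grid
        out = np.stack([np.interp(pos, np.arange(n_valid), ch) for ch in sm])
    return rec.copy_with(data=out, fs=target_fs)


def power_envelope(rec: Recording, window_s: float = 1.0) -> Recording:
    """RMS band-power envelope: sliding mean of the squared signal, square
    root.  This is the slow representation of EEG that can be meaningfully
    correlated with (and fused against) hemodynamics — a plain 1-s average
    of an oscillation is ~0, its power envelope is not.
    """
    sq = rec.copy_with(data=rec.data ** 2)
    sm = moving_average_downsize(sq, window_s=window_s, target_fs=rec.fs)
    env = np.sqrt(np.maximum(sm.data, 0.0))
    # the valid sliding mean is w-1 samples short; edge-pad so sample
    # indexing (and trial onsets) stays aligned with the source recording
    deficit = rec.n_samples - env.shape[1]
    if deficit > 0:
        env = np.pad(env, ((0, 0), (0, deficit)), mode="edge")
    return rec.copy_with(data=env)


def synchronize(*recs: Recording, target_fs: float = 10.0) -> list[Recording]:
    """Bring recordings onto a shared grid at ``target_fs`` and equal length."""
    out = []
    for rec in recs:
        if rec.fs == target_fs:
            out.append(rec)
        elif rec.fs > target_fs:
            out.append(downsample(rec, target_fs))
        else:
            up, down = _ratio(target_fs, rec.fs)
            out.append(rec.copy_with(
                data=sg.resample_poly(rec.data, up, down, axis=1), fs=target_fs))
    n = min(r.n_samples for r in out)
    return [r.copy_with(data=r.data[:, :n]) for r in out]


# ---------------------------------------------------------------------------
# dataset presets
# ---------------------------------------------------------------------------

def _preset_buccino(eeg: Recording | None, hbo: Recording | None,
                    hbr: Recording | None):
    out = {}
    if eeg is not None:
        out["eeg"] = butterworth_filter(
            eeg, FilterSpec("bandpass", 1.0, 50.0, order=4, zero_phase=False))
    # zero-phase for the hemodynamic band: a causal 0.01-0.2 Hz band-pass
    # delays the ~0.08 Hz trial-cycle component by several seconds, which
    # would misalign every trial window with its own response
    spec = FilterSpec("bandpass", 0.01, 0.2, order=4, zero_phase=True)
    if hbo is not None:
        out["hbo"] = butterworth_filter(hbo, spec)
    if hbr is not None:
        out["hbr"] = butterworth_filter(hbr, spec)
    return out


def _preset_tuberlin(eeg, hbo, hbr):
    out = {}
    if eeg is not None:
        e = downsample(eeg, 200.0) if eeg.fs > 200.0 else eeg
        out["eeg"] = butterworth_filter(
            e, FilterSpec("bandpass", 1.0, 40.0, order=6, zero_phase=True))
    spec = FilterSpec("lowpass", None, 0.2, order=6, zero_phase=True)
    for key, rec in (("hbo", hbo), ("hbr", hbr)):
        if rec is not None:
            r = downsample(rec, 10.0) if rec.fs > 10.0 else rec
            out[key] = butterworth_filter(r, spec)
    return out


PRESETS: dict[str, Callable] = {
    "buccino": _preset_buccino,
    "synthetic": _preset_buccino,   # generator runs at the buccino-style rates
    "tuberlin": _preset_tuberlin,
}


def apply_preset(name: str, eeg: Recording | None = None,
                 hbo: Recording | None = None,
                 hbr: Recording | None = None) -> dict[str, Recording]:
    """Run one dataset preset's filtering chain; returns the filtered
    recordings keyed 'eeg'/'hbo'/'hbr' (only the ones supplied)."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return PRESETS[name](eeg, hbo, hbr)


def ocular_artifact_hook(rec: Recording,
                         method: Callable[[np.ndarray], np.ndarray] | None = None
                         ) -> Recording:
    """Pluggable ocular-artifact removal stage.

    Blind-source ocular cleanup is outside this package; pass a callable
    mapping a (channels, samples) array to its cleaned version to slot one
    in.  With ``method=None`` the recording passes through unchanged.
    """
    if method is None:
        return rec
    return rec.copy_with(data=np.asarray(method(rec.data), dtype=float))
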