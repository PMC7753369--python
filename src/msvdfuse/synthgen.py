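"""Synthetic paired EEG + fNIRS sessions with known class structure.

The generator emulates a block-design motor protocol: each trial is 6 s of
rest followed by 6 s of task, EEG sampled at 250 Hz and fNIRS at 10.42 Hz,
with four task classes plus an explicit rest class.  Its purpose is to give
every downstream stage (preprocessing, channel selection, fusion,
classification) a ground truth to be checked against offline.

What is planted, per informative channel pair i (EEG channel i with HbO
channel i):

* EEG — class-dependent amplitude modulation of 10 Hz and 20 Hz oscillations
  during task windows (smooth 0.5 s onset/offset ramps), on a 1/f-shaped
  background.
* HbO — the same class-dependent boxcar convolved with a canonical
  double-gamma hemodynamic response, plus sinusoidal physiological
  oscillations near 0.1 Hz (Mayer waves), 0.3 Hz (respiration) and 1.2 Hz
  (cardiac) and white noise; HbR is a negatively scaled copy of the
  hemodynamic component with its own noise.
* A per-trial gain jitter shared *within* a pair (and independent across
  pairs) so that matched channels correlate more strongly than unmatched
  ones — the ground truth for correlation-based channel selection.

The default class structure is a *spatial* code modeled on a four-task motor
protocol (think right hand / left hand / right foot / left foot, plus rest):
the informative channels of each modality split into two regions, EEG
regions respond by effector (hand classes drive one region, foot classes the
other — somatotopy), fNIRS regions respond by body side (hemispheric
lateralization).  Either modality alone therefore confuses one class
attribute while the joint signal identifies every class — the premise of a
hybrid interface, and what lets a fusion stage demonstrably beat either
single modality.  Because the code lives in the spatial pattern, spatially
averaged summary statistics lose most of it while per-channel waveform
features retain it.  ``spatial_code=False`` switches to a plain
amplitude-per-class code for analytically predictable tests.

All randomness flows from one seed through per-modality child generators, so
outputs are byte-identical across calls and adding channels to one modality
does not perturb the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .signal_io import Modality, Recording, TrialAnnotation

__all__ = ["SynthConfig", "canonical_hrf", "gen_eeg", "gen_fnirs", "gen_hybrid"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic session.

    ``eeg_snr`` / ``nirs_snr`` are linear amplitude ratios of a unit-amplitude
    class response to the background noise; noise scales as 1/snr, so the
    snr → ∞ limit is noiseless.  ``eeg_class_amps`` / ``nirs_class_amps``
    override the built-in complementary amplitude tables (index = class id,
    class 0 is rest with amplitude 0).
    """

    n_classes: int = 5
    trials_per_class: int = 40
    eeg_fs: float = 250.0
    nirs_fs: float = 10.42
    rest_s: float = 6.0
    task_s: float = 6.0
    n_channels: int = 12
    n_informative: int = 6
    eeg_snr: float = 1.0
    nirs_snr: float = 1.0
    seed: int = 0
    eeg_class_amps: tuple | None = None
    nirs_class_amps: tuple | None = None
    pair_gain_sd: float = 0.3
    spatial_code: bool = True
    region_base: float = 0.25    # off-region response as a fraction of full

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if not (0 <= self.n_informative <= self.n_channels):
            raise ValueError("n_informative must be in [0, n_channels]")
        if min(self.rest_s, self.task_s) <= 0:
            raise ValueError("durations must be > 0")
        if min(self.eeg_fs, self.nirs_fs) <= 0:
            raise ValueError("sampling rates must be > 0")

    # -- derived protocol quantities ------------------------------------
    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class

    @property
    def trial_s(self) -> float:
        return self.rest_s + self.task_s

    @property
    def duration_s(self) -> float:
        # one extra rest block at the end so smoothing windows stay in range
        return self.n_trials * self.trial_s + self.rest_s

    def class_amps(self, modality: str) -> np.ndarray:
        """Class-amplitude table (index = class id; class 0 = rest = 0)."""
        override = self.eeg_class_amps if modality == "eeg" else self.nirs_class_amps
        if override is not None:
            amps = np.asarray(override, dtype=float)
            if len(amps) != self.n_classes:
                raise ValueError("class amplitude table length must equal n_classes")
            return amps
        amps = np.full(self.n_classes, 1.5)
        amps[0] = 0.0
        return amps

    def class_weights(self, modality: str) -> np.ndarray:
        """(n_classes, n_informative) response weight of each informative
        channel to each class.

        With the spatial code on, channels split into two regions and each
        task class drives its own region at full weight, the other at
        ``region_base``: EEG regions follow the class's *effector* attribute
        (classes grouped in consecutive pairs), fNIRS regions its *side*
        attribute (alternating classes).  Class 0 (rest) drives nothing.
        """
        amps = self.class_amps(modality)
        n_inf = self.n_informative
        W = np.tile(amps[:, None], (1, max(n_inf, 1)))
        if not self.spatial_code or n_inf == 0:
            return W[:, :n_inf]
        half = (n_inf + 1) // 2
        region = (np.arange(n_inf) >= half).astype(int)
        for c in range(1, self.n_classes):
            attr = ((c - 1) // 2) % 2 if modality == "eeg" else (c - 1) % 2
            w = np.where(region == attr, 1.0, self.region_base)
            W[c] = amps[c] * w
        return W


def canonical_hrf(t, peak_s: float = 6.0, undershoot_s: float = 16.0,
                  ratio: float = 1.0 / 6.0):
    """Canonical double-gamma hemodynamic impulse response.

    Difference of two gamma densities: a positive lobe peaking near
    ``peak_s`` and an undershoot peaking near ``undershoot_s`` scaled by
    ``ratio``; the curve is 0 at t = 0 and decays to 0 for large t.  Unit
    time scale (dispersion 1 s per gamma), values normalized so the peak of
    the positive lobe is ~1.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("canonical_hrf is defined for t >= 0")
    # gamma density with mode at peak_s when shape = peak_s + 1, scale 1
    main = sps.gamma.pdf(t, a=peak_s + 1.0, scale=1.0)
    under = sps.gamma.pdf(t, a=undershoot_s + 1.0, scale=1.0)
    h = main / sps.gamma.pdf(peak_s, a=peak_s + 1.0, scale=1.0) \
        - ratio * under / sps.gamma.pdf(undershoot_s, a=undershoot_s + 1.0, scale=1.0)
    return float(h) if h.ndim == 0 else h


# ---------------------------------------------------------------------------
# internal builders
# ---------------------------------------------------------------------------

def _protocol(cfg: SynthConfig, fs: float) -> TrialAnnotation:
    rng = np.random.default_rng([cfg.seed, 0])   # protocol substream
    labels = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)
    rng.shuffle(labels)
    onsets_s = cfg.rest_s + np.arange(cfg.n_trials) * cfg.trial_s
    onsets = np.round(onsets_s * fs).astype(int)
    return TrialAnnotation(onsets, labels, cfg.rest_s, cfg.task_s)


def _pair_gains(cfg: SynthConfig) -> np.ndarray:
    """(n_informative, n_trials) per-trial gain jitter, shared within a pair."""
    rng = np.random.default_rng([cfg.seed, 1])
    g = 1.0 + cfg.pair_gain_sd * rng.standard_normal((max(cfg.n_informative, 1),
                                                      cfg.n_trials))
    return np.clip(g, 0.1, None)


def _boxcar_drive(cfg: SynthConfig, fs: float, W: np.ndarray,
                  gains: np.ndarray, chan: int, n: int,
                  ann: TrialAnnotation, ramp_s: float = 0.0) -> np.ndarray:
    """Per-channel task drive: class-weighted boxcar over task windows."""
    drive = np.zeros(n)
    win = int(round(cfg.task_s * fs))
    ramp = int(round(ramp_s * fs))
    for t_idx, (onset, lab) in enumerate(zip(ann.onsets, ann.labels)):
        a = W[int(lab), chan] * gains[chan, t_idx]
        if a == 0.0:
            continue
        seg = np.full(win, a)
        if ramp > 0 and 2 * ramp < win:
            r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
            seg[:ramp] *= r
            seg[-ramp:] *= r[::-1]
        drive[onset:onset + win] = seg[: max(0, n - onset)]
    return drive


def _one_over_f_noise(rng, n_channels: int, n: int) -> np.ndarray:
    """Unit-RMS noise with ~1/f amplitude spectrum (EEG-like background)."""
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:] / f[1])
    shaped = np.fft.irfft(spec * shaping, n=n, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    return shaped / rms


def gen_eeg(cfg: SynthConfig) -> tuple[Recording, TrialAnnotation]:
    """Synthesize the EEG half of a session (see module docstring)."""
    fs = cfg.eeg_fs
    n = int(round(cfg.duration_s * fs))
    ann = _protocol(cfg, fs)
    rng = np.random.default_rng([cfg.seed, 2])
    W = cfg.class_weights("eeg")
    gains = _pair_gains(cfg)
    t = np.arange(n) / fs
    noise_scale = 0.0 if np.isinf(cfg.eeg_snr) else 1.0 / cfg.eeg_snr
    noise = _one_over_f_noise(rng, cfg.n_channels, n)
    data = noise_scale * noise
    for ch in range(cfg.n_informative):
        drive = _boxcar_drive(cfg, fs, W, gains, ch, n, ann, ramp_s=0.5)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        carrier = np.sin(2 * np.pi * 10.0 * t + ph1) + 0.5 * np.sin(2 * np.pi * 20.0 * t + ph2)
        data[ch] += drive * carrier
    names = [f"eeg{i + 1:02d}" for i in range(cfg.n_channels)]
    rec = Recording(data, fs=fs, channel_names=names, modality=Modality.EEG, units="uV")
    return rec, ann


def gen_fnirs(cfg: SynthConfig) -> tuple[Recording, Recording, TrialAnnotation]:
    """Synthesize the fNIRS half: HbO, HbR and the trial annotation."""
    fs = cfg.nirs_fs
    n = int(round(cfg.duration_s * fs))
    ann = _protocol(cfg, fs)
    rng = np.random.default_rng([cfg.seed, 3])
    W = cfg.class_weights("nirs")
    gains = _pair_gains(cfg)
    t = np.arange(n) / fs
    hrf = canonical_hrf(np.arange(0, 32.0, 1.0 / fs))
    # normalize so a unit-amplitude task boxcar yields a unit peak response
    unit_box = np.ones(int(round(cfg.task_s * fs)))
    hrf = hrf / np.convolve(unit_box, hrf).max()
    noise_scale = 0.0 if np.isinf(cfg.nirs_snr) else 1.0 / cfg.nirs_snr

    def physio(r):
        out = np.zeros(n)
        for f0, a in ((0.1, 0.4), (0.3, 0.3), (1.2, 0.2)):
            out += a * np.sin(2 * np.pi * f0 * t + r.uniform(0, 2 * np.pi))
        return out

    hbo = np.empty((cfg.n_channels, n))
    hbr = np.empty_like(hbo)
    for ch in range(cfg.n_channels):
        if ch < cfg.n_informative:
            drive = _boxcar_drive(cfg, fs, W, gains, ch, n, ann)
            resp = np.convolve(drive, hrf)[:n]
        else:
            resp = np.zeros(n)
        hbo[ch] = resp + noise_scale * (physio(rng) + 0.5 * rng.standard_normal(n))
        hbr[ch] = -0.4 * resp + noise_scale * (physio(rng) + 0.25 * rng.standard_normal(n))
    names = [f"nirs{i + 1:02d}" for i in range(cfg.n_channels)]
    mk = lambda d, mod: Recording(d, fs=fs, channel_names=list(names),
                                  modality=mod, units="mM")
    return mk(hbo, Modality.HBO), mk(hbr, Modality.HBR), ann


def gen_hybrid(cfg: SynthConfig):
    """Concurrent EEG + fNIRS session sharing one protocol and pair gains.

    Returns ``(eeg, hbo, hbr, ann_eeg, ann_nirs)``: the two annotations
    carry the same labels and times, expressed at each modality's rate.
    """
    eeg, ann_eeg = gen_eeg(cfg)
    hbo, hbr, ann_nirs = gen_fnirs(cfg)
    return eeg, hbo, hbr, ann_eeg, ann_nirs
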