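"""Domain containers and delimited-text I/O for multichannel recordings.

A :class:`Recording` is one modality's channels-by-samples matrix plus its
sampling rate; a :class:`TrialAnnotation` marks task onsets within it; an
:class:`Epochs` object holds the trial-segmented windows used by feature
extraction and classification.

Files are plain delimited text (comma or tab, auto-detected), one row per
channel, optional header row of channel names, ``#`` comment lines.  This is
deliberately the simplest portable interchange format; MATLAB v5 containers
used by public hybrid-BCI datasets are reachable through the (unimplemented)
adapter hook at the bottom of the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Modality",
    "Recording",
    "TrialAnnotation",
    "Epochs",
    "read_recording",
    "write_recording",
    "epoch",
    "read_config",
    "write_config",
    "load_mat_adapter",
]


class Modality(str, Enum):
    """What a recording's samples physically are."""

    EEG = "EEG"
    NIRS_INTENSITY = "NIRS_INTENSITY"
    HBO = "HBO"
    HBR = "HBR"


@dataclass
class Recording:
    """One modality's multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Finite sample values; rows are channels.
    fs : float
        Sampling rate in Hz, > 0.
    channel_names : list of str
        Unique names, one per row.
    modality : Modality
        Constrains downstream operations (e.g. MBLL accepts only
        ``NIRS_INTENSITY``).
    units : str
        Free-form unit label (µV, µM, ...).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    modality: Modality = Modality.EEG
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        self.modality = Modality(self.modality)
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        """Shallow variant constructor (data is not copied unless replaced)."""
        return replace(self, **kw)


@dataclass
class TrialAnnotation:
    """Task-onset markers for one recording.

    Onsets are 0-based sample indices at the recording's own sampling rate,
    strictly increasing; ``labels`` gives one class id per onset.  The rest
    period of each trial is the ``rest_duration_s`` window ending at the
    onset.
    """

    onsets: np.ndarray
    labels: np.ndarray
    rest_duration_s: float
    task_duration_s: float

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.labels = np.asarray(self.labels)
        if self.onsets.ndim != 1 or self.labels.shape != self.onsets.shape:
            raise ValueError("onsets and labels must be 1-D and the same length")
        if len(self.onsets) and self.onsets[0] < 0:
            raise ValueError("onsets must be non-negative")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.rest_duration_s <= 0 or self.task_duration_s <= 0:
            raise ValueError("durations must be > 0")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    def at_rate(self, old_fs: float, new_fs: float) -> "TrialAnnotation":
        """Re-express onsets at a different sampling rate (nearest sample)."""
        onsets = np.round(self.onsets * (new_fs / old_fs)).astype(int)
        return TrialAnnotation(onsets, self.labels.copy(),
                               self.rest_duration_s, self.task_duration_s)


@dataclass
class Epochs:
    """Trial-segmented windows: ``data`` is (trials, channels, samples)."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("epochs data must be 3-D (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1:02d}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_channels(self, names: Sequence[str]) -> "Epochs":
        """Subset (and reorder) channels by name."""
        idx = []
        for nm in names:
            if nm not in self.channel_names:
                raise KeyError(f"unknown channel {nm!r}")
            idx.append(self.channel_names.index(nm))
        return Epochs(self.data[:, idx, :], self.labels.copy(), self.fs, list(names))


# ---------------------------------------------------------------------------
# delimited text I/O
# ---------------------------------------------------------------------------

def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_recording(path, fs: float, modality=Modality.EEG, units: str = "") -> Recording:
    """Read a delimited numeric matrix (rows = channels) into a Recording.

    The first non-comment row is treated as a header of channel names when any
    of its cells is non-numeric; otherwise names ``ch01`` ... are generated.
    Non-numeric or non-finite cells raise with their row/column position.
    """
    lines = []
    for raw in Path(path).read_text().splitlines():
        if raw.strip() == "" or raw.lstrip().startswith("#"):
            continue
        lines.append(raw)
    if not lines:
        raise ValueError(f"{path}: no data rows")

    delim = _sniff_delimiter(lines[0])
    first = [c.strip() for c in lines[0].split(delim)]

    def _try_float(tok: str):
        try:
            return float(tok)
        except ValueError:
            return None

    header: list[str] | None = None
    if any(_try_float(tok) is None for tok in first):
        header = first
        lines = lines[1:]
        if not lines:
            raise ValueError(f"{path}: header but no data rows")

    rows: list[list[float]] = []
    width = None
    for i, ln in enumerate(lines):
        toks = [c.strip() for c in ln.split(delim)]
        if width is None:
            width = len(toks)
        elif len(toks) != width:
            raise ValueError(
                f"{path}: ragged row {i + 1}: {len(toks)} columns, expected {width}"
            )
        vals = []
        for j, tok in enumerate(toks):
            v = _try_float(tok)
            if v is None or not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-numeric or non-finite cell at row {i + 1}, column {j + 1}: {tok!r}"
                )
            vals.append(v)
        rows.append(vals)

    data = np.array(rows, dtype=float)
    if header is None:
        names = [f"ch{i + 1:02d}" for i in range(data.shape[0])]
    else:
        names = header
    return Recording(data, fs=fs, channel_names=names, modality=modality, units=units)


def _fmt(v: float) -> str:
    # shortest repr round-trips float64 exactly
    return repr(float(v))


def write_recording(path, rec: Recording, delimiter: str = ",") -> None:
    """Write a Recording as delimited text with a channel-name header.

    Values are printed with shortest-round-trip precision so read/write
    reproduces them bit-for-bit.
    """
    with open(path, "w") as fh:
        fh.write(delimiter.join(rec.channel_names) + "\n")
        for row in rec.data:
            fh.write(delimiter.join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# epoching
# ---------------------------------------------------------------------------

def epoch(rec: Recording, ann: TrialAnnotation, include_rest: bool = False,
          rest_label="rest") -> Epochs:
    """Cut task windows (and optionally the preceding rest windows) out of a
    recording.

    Each trial is the half-open window ``[onset, onset + round(task_s * fs))``.
    With ``include_rest=True`` a rest epoch of the same length, ending at the
    onset, is added per trial and labelled ``rest_label``.
    """
    win = int(round(ann.task_duration_s * rec.fs))
    if win < 1:
        raise ValueError("task window shorter than one sample")
    trials, labels = [], []
    for onset, lab in zip(ann.onsets, ann.labels):
        if onset + win > rec.n_samples:
            raise ValueError(
                f"trial at sample {onset} + {win} exceeds recording length {rec.n_samples}"
            )
        if include_rest:
            if onset - win < 0:
                raise ValueError(f"rest window before sample {onset} underruns the recording")
            trials.append(rec.data[:, onset - win:onset])
            labels.append(rest_label)
        trials.append(rec.data[:, onset:onset + win])
        labels.append(lab)
    return Epochs(np.stack(trials), np.asarray(labels), rec.fs, list(rec.channel_names))


# ---------------------------------------------------------------------------
# flat key=value run configuration
# ---------------------------------------------------------------------------

def read_config(path) -> dict[str, str]:
    """Parse a flat ``key = value`` text file ('#' comments allowed)."""
    cfg: dict[str, str] = {}
    for i, raw in enumerate(Path(path).read_text().splitlines()):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {i + 1} is not 'key = value': {line!r}")
        key, _, val = line.partition("=")
        cfg[key.strip()] = val.strip()
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k} = {v}\n")


# ---------------------------------------------------------------------------
# dataset adapter hook
# ---------------------------------------------------------------------------

def load_mat_adapter(path, variable: str, fs: float, modality: Modality) -> Recording:
    """Adapter hook for MATLAB v5 containers used by public hybrid-BCI
    datasets (motor-execution and n-back corpora distributed as ``.mat``).

    Deliberately unimplemented: external-dataset parsing is outside the tested
    path.  An adapter should return a :class:`Recording` with the matrix in
    ``variable`` oriented channels-by-samples.
    """
    raise NotImplementedError(
        "external dataset adapters are not part of the tested pipeline; "
        "convert your data to delimited text and use read_recording()"
    )
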