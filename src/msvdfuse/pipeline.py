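"""End-to-end experiment orchestration.

The full chain is: synthesize (or load) a session -> dataset-preset filtering
-> baseline standardization -> EEG band-power envelope -> synchronization of
both modalities onto a common 10 Hz grid -> correlation-based channel
selection -> epoching -> (optionally) MSVD fusion -> feature extraction ->
stratified cross-validated classification.

Four experiment families mirror the evaluation design:

* ``run_unimodal_eeg``   — DWT approximation features A_1..A_4 per selected
  channel, one report per level;
* ``run_unimodal_fnirs`` — all 15 unordered pairs of the six statistical
  features of the spatially averaged selected HbO channels;
* ``run_hybrid``         — feature-based or system-based MSVD fusion with a
  DWT / statistical / combined feature set;
* ``benchmark``          — the 4 x 2 grid of pipelines x classifiers.

Channel selection runs once per session on the full filtered recordings by
default (the once-per-subject convention); a strict mode re-selects inside
every training fold and is available via ``per_fold_selection=True``.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import MinMaxScaler

from . import channel_select, features, fusion, preprocess, synthgen
from .classify import (ClassifierSpec, FeatureTable, MetricsReport,
                       compute_metrics, cross_validate, _fingerprint,
                       _fit_predict)
from .features import STAT_FEATURE_NAMES, minmax_normalize, stat_features
from .signal_io import Epochs, Recording, epoch

__all__ = [
    "RunConfig",
    "PreparedSession",
    "prepare_session",
    "run_unimodal_eeg",
    "run_unimodal_fnirs",
    "run_hybrid",
    "benchmark",
]

log = logging.getLogger("msvdfuse")
COMMON_FS = 10.0          # synchronization grid shared by both modalities
DWT_LEVEL = 4             # deepest approximation used as the EEG feature


@dataclass(frozen=True)
class RunConfig:
    """One experiment's knobs (see module docstring for the stages)."""

    preset: str = "synthetic"
    k_channels: int = 6
    scheme: str = "system"              # "feature" | "system"
    feature_set: str = "dwt"            # "dwt" | "stats" | "dwt+stats"
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    folds: int = 10
    msvd_levels: int = 1
    seed: int = 42
    synth: synthgen.SynthConfig | None = None

    def synth_config(self) -> synthgen.SynthConfig:
        return self.synth if self.synth is not None else synthgen.SynthConfig(seed=self.seed)


@dataclass
class PreparedSession:
    """Conditioned, synchronized, channel-selected data for one session."""

    eeg_env_native: Recording        # band-power envelope at the EEG rate
    eeg_env_common: Recording        # same, on the common grid (z-scored)
    hbo_native: Recording            # filtered HbO at its own rate (z-scored)
    hbo_common: Recording            # on the common grid (z-scored)
    ann_native_eeg: "object"
    ann_native_nirs: "object"
    ann_common: "object"
    ranking: channel_select.ChannelRanking

    @property
    def selected_eeg(self) -> list[str]:
        return self.ranking.selected_eeg

    @property
    def selected_nirs(self) -> list[str]:
        return self.ranking.selected_nirs


def _stage(name: str, t0: float, **info) -> None:
    extras = " ".join(f"{k}={v}" for k, v in info.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, extras)


def prepare_session(cfg: RunConfig) -> PreparedSession:
    """Generate and condition one synthetic session up to channel selection."""
    t0 = time.perf_counter()
    scfg = cfg.synth_config()
    eeg, hbo, hbr, ann_e, ann_n = synthgen.gen_hybrid(scfg)
    _stage("simulate", t0, trials=ann_e.n_trials, eeg_fs=eeg.fs, nirs_fs=hbo.fs)

    t0 = time.perf_counter()
    filt = preprocess.apply_preset(cfg.preset, eeg=eeg, hbo=hbo, hbr=hbr)
    eeg_f = preprocess.baseline_standardize(filt["eeg"])
    hbo_f = preprocess.baseline_standardize(filt["hbo"])
    env = preprocess.power_envelope(eeg_f, window_s=1.0)
    env_c, hbo_c = preprocess.synchronize(env, hbo_f, target_fs=COMMON_FS)
    env_c = preprocess.baseline_standardize(env_c)
    hbo_c = preprocess.baseline_standardize(hbo_c)
    _stage("preprocess", t0, common_fs=COMMON_FS,
           shapes=f"{env_c.data.shape}/{hbo_c.data.shape}")

    t0 = time.perf_counter()
    ranking = channel_select.rank_channels(env_c, hbo_c, k=cfg.k_channels,
                                           envelope=False)
    _stage("select-channels", t0, eeg=",".join(ranking.selected_eeg),
           nirs=",".join(ranking.selected_nirs))

    ann_common = ann_e.at_rate(eeg.fs, COMMON_FS)
    return PreparedSession(
        eeg_env_native=env, eeg_env_common=env_c, hbo_native=hbo_f,
        hbo_common=hbo_c, ann_native_eeg=ann_e, ann_native_nirs=ann_n,
        ann_common=ann_common, ranking=ranking,
    )


# ---------------------------------------------------------------------------
# feature builders
# ---------------------------------------------------------------------------

def _capped_level(n_samples: int, requested: int = DWT_LEVEL) -> int:
    filt = features.WaveletFilters.from_name("sym4")
    return min(requested, features.max_decomposition_level(n_samples, filt.F))

def dwt_feature_table(epochs: Epochs, level: int = DWT_LEVEL,
                      channels=None) -> FeatureTable:
    """Per-trial features: level-``level`` DWT approximation coefficients of
    each (selected) channel, concatenated.  The level is capped at the
    deepest one the trial length supports."""
    ep = epochs.select_channels(channels) if channels is not None else epochs
    lvl = _capped_level(ep.n_samples, level)
    filt = features.WaveletFilters.from_name("sym4")
    rows, names = [], []
    for t in range(ep.n_trials):
        feats = []
        for c in range(ep.n_channels):
            A = features.dwt_decompose(ep.data[t, c], lvl, filt).approximations[-1]
            feats.append(A)
            if t == 0:
                names += [f"A{lvl}_{ep.channel_names[c]}_{i + 1}" for i in range(len(A))]
        rows.append(np.concatenate(feats))
    return FeatureTable(np.stack(rows), ep.labels.copy(), names)


def stats_feature_table(epochs: Epochs, channels=None,
                        pair: tuple[str, str] | None = None) -> FeatureTable:
    """Per-trial statistical features of the spatially averaged channels.

    With ``pair`` given, only those two of (M, P, SK, KR, SD, VAR) are kept.
    """
    ep = epochs.select_channels(channels) if channels is not None else epochs
    avg = features.spatial_average(ep, ep.channel_names)
    rows = np.stack([stat_features(avg[t], partial=True) for t in range(ep.n_trials)])
    names = list(STAT_FEATURE_NAMES)
    if np.isnan(rows).any():
        bad = np.isnan(rows).any(axis=1)
        log.warning("dropping %d degenerate (constant) trial(s)", int(bad.sum()))
        rows, labels = rows[~bad], ep.labels[~bad]
    else:
        labels = ep.labels.copy()
    if pair is not None:
        idx = [names.index(p) for p in pair]
        rows, names = rows[:, idx], [names[i] for i in idx]
    return FeatureTable(rows, labels, names)


def _eeg_scalar_features(epochs: Epochs, level: int = DWT_LEVEL,
                         reduction: str = "mean") -> np.ndarray:
    """One scalar per channel per trial: mean (or power) of its normalized
    deepest-approximation vector, then rescaled to [0, 1] per channel across
    trials so the two modalities enter fusion on a common scale."""
    lvl = _capped_level(epochs.n_samples, level)
    filt = features.WaveletFilters.from_name("sym4")
    out = np.empty((epochs.n_trials, epochs.n_channels))
    for t in range(epochs.n_trials):
        for c in range(epochs.n_channels):
            A = features.dwt_decompose(epochs.data[t, c], lvl, filt).approximations[-1]
            out[t, c] = np.mean(A) if reduction == "mean" else np.mean(A ** 2)
    return np.stack([minmax_normalize(col) for col in out.T], axis=1)


def _fnirs_scalar_features(epochs: Epochs) -> np.ndarray:
    """The six statistical features of the spatial average, each rescaled to
    [0, 1] across trials (the Eq.-style feature normalization)."""
    table = stats_feature_table(epochs)
    return np.stack([minmax_normalize(col) for col in table.X.T], axis=1)


# ---------------------------------------------------------------------------
# experiment families
# ---------------------------------------------------------------------------

def _epochs_native_eeg(sess: PreparedSession) -> Epochs:
    return epoch(sess.eeg_env_native, sess.ann_native_eeg)


def _epochs_native_hbo(sess: PreparedSession) -> Epochs:
    return epoch(sess.hbo_native, sess.ann_native_nirs)


def _epochs_common(sess: PreparedSession) -> tuple[Epochs, Epochs]:
    e = epoch(sess.eeg_env_common, sess.ann_common)
    n = epoch(sess.hbo_common, sess.ann_common)
    return e, n


def run_unimodal_eeg(cfg: RunConfig, sess: PreparedSession | None = None
                     ) -> dict[int, MetricsReport]:
    """EEG-only classification from A_1..A_4 features; one report per level."""
    sess = sess or prepare_session(cfg)
    ep = _epochs_native_eeg(sess).select_channels(sess.selected_eeg)
    lmax = _capped_level(ep.n_samples, DWT_LEVEL)
    if lmax < DWT_LEVEL:
        log.warning("trials support only %d DWT level(s); reporting up to A%d",
                    lmax, lmax)
    reports = {}
    for lvl in range(1, lmax + 1):
        table = dwt_feature_table(ep, level=lvl)
        reports[lvl] = cross_validate(table, cfg.classifier, cfg.folds, cfg.seed)
    return reports


def run_unimodal_fnirs(cfg: RunConfig, sess: PreparedSession | None = None
                       ) -> dict[tuple[str, str], MetricsReport]:
    """fNIRS-only classification for all 15 statistical feature pairs."""
    sess = sess or prepare_session(cfg)
    ep = _epochs_native_hbo(sess).select_channels(sess.selected_nirs)
    reports = {}
    for pair in itertools.combinations(STAT_FEATURE_NAMES, 2):
        table = stats_feature_table(ep, pair=pair)
        reports[pair] = cross_validate(table, cfg.classifier, cfg.folds, cfg.seed)
    return reports


def _hybrid_table(cfg: RunConfig, sess: PreparedSession) -> FeatureTable:
    """Build the fused feature table for the configured scheme/feature set."""
    ep_e, ep_n = _epochs_common(sess)
    ep_e = ep_e.select_channels(sess.selected_eeg)
    ep_n = ep_n.select_channels(sess.selected_nirs)
    if cfg.scheme == "feature":
        fe = _eeg_scalar_features(ep_e)
        fn = _fnirs_scalar_features(ep_n)
        fused = fusion.feature_based_fusion(fe, fn, L=cfg.msvd_levels)
        return FeatureTable(fused, ep_e.labels.copy(),
                            [f"fused{i + 1}" for i in range(6)])
    if cfg.scheme == "system":
        fused_ep = fusion.system_based_fusion(ep_e, ep_n, L=cfg.msvd_levels)
        tables = []
        if "dwt" in cfg.feature_set:
            tables.append(dwt_feature_table(fused_ep))
        if "stats" in cfg.feature_set:
            tables.append(stats_feature_table(fused_ep))
        if not tables:
            raise ValueError(f"empty feature set {cfg.feature_set!r}")
        X = np.hstack([t.X for t in tables])
        names = sum((t.feature_names for t in tables), [])
        return FeatureTable(X, tables[0].y, names)
    raise ValueError(f"unknown scheme {cfg.scheme!r}")


def run_hybrid(cfg: RunConfig, sess: PreparedSession | None = None,
               per_fold_selection: bool = False) -> MetricsReport:
    """Hybrid EEG-fNIRS classification through the configured fusion scheme.

    The report's fingerprint records the selected channels and fusion depth.
    """
    sess = sess or prepare_session(cfg)
    if per_fold_selection:
        return _run_hybrid_per_fold(cfg, sess)
    table = _hybrid_table(cfg, sess)
    report = cross_validate(table, cfg.classifier, cfg.folds, cfg.seed)
    report.fingerprint += (
        f"|scheme={cfg.scheme}|features={cfg.feature_set}|L={cfg.msvd_levels}"
        f"|eeg={','.join(sess.selected_eeg)}|nirs={','.join(sess.selected_nirs)}"
    )
    return report


def _run_hybrid_per_fold(cfg: RunConfig, sess: PreparedSession) -> MetricsReport:
    """Strict variant: channel selection repeated inside every training fold
    using only that fold's trials (concatenated along time)."""
    ep_e_all, ep_n_all = _epochs_common(sess)
    y = ep_e_all.labels
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    classes = np.unique(y)
    accs, specs, aucs = [], [], []
    cm_total = np.zeros((len(classes), len(classes)), dtype=int)
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        eeg_cat = Recording(
            np.concatenate(ep_e_all.data[tr_idx], axis=1), fs=ep_e_all.fs,
            channel_names=ep_e_all.channel_names)
        hbo_cat = Recording(
            np.concatenate(ep_n_all.data[tr_idx], axis=1), fs=ep_n_all.fs,
            channel_names=ep_n_all.channel_names)
        ranking = channel_select.rank_channels(eeg_cat, hbo_cat,
                                               k=cfg.k_channels, envelope=False)
        fold_sess = replace(sess, ranking=ranking)
        table = _hybrid_table(cfg, fold_sess)
        scaler = MinMaxScaler().fit(table.X[tr_idx])
        pred, scores, cls = _fit_predict(
            cfg.classifier, scaler.transform(table.X[tr_idx]), y[tr_idx],
            scaler.transform(table.X[te_idx]), seed=cfg.seed)
        a, s, u = compute_metrics(y[te_idx], pred, scores, classes)
        accs.append(a); specs.append(s); aucs.append(u)
        cm_total += confusion_matrix(y[te_idx], pred, labels=classes)
    return MetricsReport(np.array(accs), np.array(specs), np.array(aucs),
                         cm_total, classes,
                         _fingerprint(cfg.classifier, cfg.folds, cfg.seed,
                                      (len(y),)) + "|per-fold-selection")


def benchmark(cfg: RunConfig) -> pd.DataFrame:
    """4 pipelines x {knn, tree} comparison on one synthetic session."""
    sess = prepare_session(cfg)
    rows = []
    for model in ("knn", "tree"):
        c = replace(cfg, classifier=replace(cfg.classifier, model=model))
        eeg_rep = run_unimodal_eeg(c, sess)
        best_lvl = max(eeg_rep)
        rows.append(("unimodal_eeg", model, eeg_rep[best_lvl]))
        fn = stats_feature_table(
            _epochs_native_hbo(sess).select_channels(sess.selected_nirs))
        rows.append(("unimodal_fnirs", model,
                     cross_validate(fn, c.classifier, c.folds, c.seed)))
        rows.append(("feature_fusion", model,
                     run_hybrid(replace(c, scheme="feature"), sess)))
        rows.append(("system_fusion", model,
                     run_hybrid(replace(c, scheme="system"), sess)))
    return pd.DataFrame(
        [(p, m, r.accuracy, r.specificity, r.auc) for p, m, r in rows],
        columns=["pipeline", "classifier", "accuracy", "specificity", "auc"],
    )
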