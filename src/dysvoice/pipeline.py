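"""End-to-end orchestration: data -> denoise -> features -> selection ->
model -> evaluation, behind one config.

Every stage's parameters and seeds are echoed into ``run_log.json`` and
all intermediate artifacts (features.csv, selection.csv, report.json,
optional denoised WAVs) are persisted in the output directory, so a rerun
with the same config reproduces the report bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import AudioSignal, SegmentPolicy, load_wav, normalize, segment_fixed, write_wav
from .denoise import GateParams, denoise
from .features import (FEATURE_NAMES, MelSpectrogramFeaturizer,
                       featurize_corpus)
from .models import (CLASSICAL_KINDS, DEEP_ARCHITECTURES,
                     NeuralSequenceClassifier, fit_classical)
from .evaluation import EvalReport, confusion, kfold_cv, metrics, roc_auc
from .select import FeatureMatrix, mutual_information_rank, rfe_select
from .synth import make_corpus

__all__ = ["PipelineConfig", "run_pipeline", "load_audio_dir"]


@dataclass
class PipelineConfig:
    """Declarative pipeline run description."""

    # data source: synthetic corpus unless audio_dir is given
    audio_dir: str | None = None
    n_pd: int = 40
    n_hc: int = 41
    jitter_spread: float = 0.4
    rate: int = 8000
    duration: float = 3.0
    # preprocessing
    apply_denoise: bool = False
    gate_k: float = 1.5
    gate_alpha: float = 0.1
    noise_frames: int = 10
    # selection (classical models only)
    selection: str = "mi"            # mi | rfe | none
    n_keep: int = 20
    # model
    model: str = "bilstm"            # deep arch or classical kind
    epochs: int | None = 12          # desk-scale default for deep models
    batch_size: int = 16
    learning_rate: float = 0.001
    # evaluation
    protocol: str = "split"          # split | kfold
    split: float = 0.8
    k: int = 10
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None
    save_wavs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def load_audio_dir(root: str | Path, rate: int = 8000,
                   duration: float = 3.0) -> list[AudioSignal]:
    """Adapter for a directory of labeled WAVs: files under ``PD/`` and
    ``HC/`` subdirectories (or with ``pd_``/``hc_`` name prefixes) are
    loaded, resampled, normalized and cut/padded to the fixed length."""
    root = Path(root)
    policy = SegmentPolicy(target_duration=duration)
    signals = []
    for path in sorted(root.rglob("*.wav")):
        name = path.name.lower()
        parent = path.parent.name.upper()
        if parent in ("PD", "HC"):
            label = parent
        elif name.startswith(("pd_", "pd-")):
            label = "PD"
        elif name.startswith(("hc_", "hc-")):
            label = "HC"
        else:
            continue
        sig = load_wav(path, target_rate=rate, label=label)
        signals.append(segment_fixed(normalize(sig), policy))
    if not signals:
        raise FileNotFoundError(f"no labeled WAV files under {root}")
    return signals


def _stratified_split(y: np.ndarray, train_fraction: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        members = members[rng.permutation(members.size)]
        cut = int(round(train_fraction * members.size))
        train_idx.extend(members[:cut])
        test_idx.extend(members[cut:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(test_idx))


def run_pipeline(config: PipelineConfig) -> tuple[EvalReport, dict]:
    """Execute the configured workflow and return (report, artifacts).

    Artifacts is a dict with the per-stage outputs; when
    ``config.out_dir`` is set they are also written to disk.
    """
    t_start = time.time()
    log: list[dict] = []

    def stage(name: str, **params) -> None:
        log.append({"stage": name, **params})

    # 1. data ---------------------------------------------------------------
    if config.audio_dir:
        signals = load_audio_dir(config.audio_dir, config.rate,
                                 config.duration)
        manifest = [{"path": "external", "label": s.label} for s in signals]
        stage("load", audio_dir=str(config.audio_dir), n=len(signals))
    else:
        corpus = make_corpus(config.n_pd, config.n_hc, config.jitter_spread,
                             seed=config.seed, rate=config.rate,
                             duration=config.duration)
        signals = corpus.signals
        manifest = corpus.manifest
        stage("synth", n_pd=config.n_pd, n_hc=config.n_hc,
              jitter_spread=config.jitter_spread, seed=config.seed)
    y = np.array([1 if s.label == "PD" else 0 for s in signals])
    if np.unique(y).size < 2:
        raise ValueError("corpus must contain both classes")

    # 2. denoise ------------------------------------------------------------
    if config.apply_denoise:
        gate = GateParams(k=config.gate_k, alpha=config.gate_alpha,
                          noise_frames=config.noise_frames)
        signals = [denoise(s, gate=gate) for s in signals]
        stage("denoise", **asdict(gate))

    # 3. features -----------------------------------------------------------
    features = featurize_corpus(signals)
    stage("extract", n_features=len(FEATURE_NAMES))

    model_name = config.model.lower()
    is_deep = model_name in DEEP_ARCHITECTURES
    if is_deep:
        grids = MelSpectrogramFeaturizer().fit_transform(signals)
        stage("mel", shape=list(grids.shape[1:]))

    # 4. selection (classical path only) ------------------------------------
    selection_frame = None
    feature_values = features[list(FEATURE_NAMES)]
    if not is_deep and config.selection != "none":
        data = FeatureMatrix.from_frame(features)
        if config.selection == "mi":
            result = mutual_information_rank(data, n_keep=config.n_keep)
        elif config.selection == "rfe":
            result = rfe_select(data, n_keep=min(config.n_keep,
                                                 data.values.shape[1] - 1))
        else:
            raise ValueError(f"unknown selection method {config.selection!r}")
        selection_frame = pd.DataFrame(result.ranked_features,
                                       columns=["feature", "score"])
        kept = [c for c in data.values.columns if c in set(result.kept)]
        feature_values = data.values[kept]
        stage("select", method=result.method, kept=len(kept))
    elif not is_deep:
        feature_values = FeatureMatrix.from_frame(features).values

    # 5/6. train + evaluate --------------------------------------------------
    if is_deep:
        X = grids

        def builder():
            return NeuralSequenceClassifier(
                arch=model_name, epochs=config.epochs,
                learning_rate=config.learning_rate,
                batch_size=config.batch_size, random_state=config.seed)
    else:
        X = feature_values.to_numpy(dtype=float)

        class _ClassicalBuilder:
            def __init__(self, kind, seed):
                self.kind, self.seed = kind, seed

            def fit(self, Xt, yt):
                self.search_ = fit_classical(self.kind, Xt, yt,
                                             seed=self.seed)
                return self

            def predict_proba(self, Xt):
                return self.search_.predict_proba(Xt)

        def builder():
            return _ClassicalBuilder(model_name, config.seed)

    if config.protocol == "kfold":
        report = kfold_cv(builder, X, y, k=config.k, seed=config.seed)
        stage("evaluate", protocol="kfold", k=config.k)
    elif config.protocol == "split":
        train_idx, test_idx = _stratified_split(y, config.split, config.seed)
        model = builder()
        model.fit(X[train_idx], y[train_idx])
        proba = np.asarray(model.predict_proba(X[test_idx]))
        scores = proba[:, 1] if proba.ndim == 2 else proba
        pred = (scores >= 0.5).astype(int)
        report = metrics(confusion(y[test_idx], pred))
        try:
            auc, roc = roc_auc(y[test_idx], scores)
            report.auc = auc
            report.roc = (tuple(roc[0]), tuple(roc[1]))
        except ValueError:
            report.undefined.append("auc")
        stage("evaluate", protocol="split", train=int(train_idx.size),
              test=int(test_idx.size))
    else:
        raise ValueError(f"unknown protocol {config.protocol!r}")

    log.append({"stage": "done", "model": model_name,
                "seconds": round(time.time() - t_start, 2)})

    artifacts = {"features": features, "selection": selection_frame,
                 "manifest": manifest, "report": report, "log": log,
                 "config": asdict(config)}

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        if selection_frame is not None:
            selection_frame.to_csv(out / "selection.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.as_dict(), fh, indent=2)
        flat = {name: getattr(report, name) for name in
                ("accuracy", "precision", "recall", "specificity",
                 "f1", "mcc", "auc")}
        pd.DataFrame([flat]).to_csv(out / "report_flat.csv", index=False)
        if report.roc is not None:
            pd.DataFrame({"fpr": report.roc[0], "tpr": report.roc[1]}
                         ).to_csv(out / "roc.csv", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump({"config": asdict(config), "log": log,
                       "manifest": manifest}, fh, indent=2, default=str)
        if config.save_wavs and not config.audio_dir:
            wav_dir = out / "wav"
            wav_dir.mkdir(exist_ok=True)
            for i, sig in enumerate(signals):
                name = f"{(sig.label or 'x').lower()}_{i:03d}.wav"
                write_wav(wav_dir / name, sig)
    return report, artifacts
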