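"""On-disk containers: flat binary arrays with JSON sidecars plus CSV tables.

Column schema of ``trials.csv`` (one row per trial, 0-based sample
indices, half-open epoch intervals): trial_index, block, condition,
target_side, target_orientation, attended_side, reported_match,
response_correct, rt, target_onset_sample.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .synth import GroundTruth, ResponseModel, SessionConfig, SessionData, TrialRecord


def _write_array(path: Path, arr: np.ndarray) -> dict:
    arr.tofile(path)
    return {"file": path.name, "dtype": str(arr.dtype), "shape": list(arr.shape)}


def _read_array(directory: Path, meta: dict) -> np.ndarray:
    arr = np.fromfile(directory / meta["file"], dtype=meta["dtype"])
    return arr.reshape(meta["shape"])


def save_session(session: SessionData, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "signal": _write_array(directory / "signal.bin", session.signal),
        "channel_labels": list(session.channel_labels),
        "sfreq": session.sfreq,
        "units": "uV",
    }
    (directory / "sidecar.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    session.trials_frame().to_csv(directory / "trials.csv", index=False,
                                  float_format="%.17g")
    if session.planted is not None:
        (directory / "ground_truth.json").write_text(
            json.dumps(session.planted.to_dict(), indent=2) + "\n")
    cfg = dataclasses.asdict(session.config)
    (directory / "config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    return directory


def load_session(directory) -> SessionData:
    directory = Path(directory)
    sidecar = json.loads((directory / "sidecar.json").read_text())
    signal = _read_array(directory, sidecar["signal"])
    trials_df = pd.read_csv(directory / "trials.csv", float_precision="round_trip")
    fields = [f.name for f in dataclasses.fields(TrialRecord)]
    trials = [TrialRecord(**{k: row[k] for k in fields})
              for row in trials_df.to_dict(orient="records")]
    planted = None
    gt_path = directory / "ground_truth.json"
    if gt_path.exists():
        d = json.loads(gt_path.read_text())
        planted = GroundTruth(
            mixing_left=np.array(d["mixing_left"]),
            mixing_right=np.array(d["mixing_right"]),
            modulation_depth=d["modulation_depth"],
            noise_amplitude=d["noise_amplitude"],
            alpha_amplitude=d["alpha_amplitude"],
            amplitude_jitter=d["amplitude_jitter"],
            alpha_band=tuple(d["alpha_band"]),
            artifact_trial_indices=set(d["artifact_trial_indices"]),
            seed=d["seed"])
    cfg_d = json.loads((directory / "config.json").read_text())
    cfg_d["rt_model"] = ResponseModel(**cfg_d["rt_model"])
    cfg_d["alpha_band"] = tuple(cfg_d["alpha_band"])
    config = SessionConfig(**cfg_d)
    return SessionData(signal=signal, channel_labels=tuple(sidecar["channel_labels"]),
                       sfreq=sidecar["sfreq"], trials=trials, planted=planted,
                       config=config)


def save_epochs(epochs: EpochSet, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "data": _write_array(directory / "epochs.bin", epochs.data),
        "eog": _write_array(directory / "eog.bin", epochs.eog),
        "sfreq": epochs.sfreq,
        "window": [epochs.window[0], int(epochs.window[1])],
        "n_rejected": epochs.n_rejected,
        "n_skipped": epochs.n_skipped,
    }
    (directory / "sidecar.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    meta = epochs.trial_meta.copy()
    if epochs.labels is not None:
        meta.insert(0, "label", epochs.labels)
    meta.to_csv(directory / "labels.csv", index=False, float_format="%.17g")
    return directory


def load_epochs(directory) -> EpochSet:
    directory = Path(directory)
    sidecar = json.loads((directory / "sidecar.json").read_text())
    meta = pd.read_csv(directory / "labels.csv", float_precision="round_trip")
    labels = None
    if "label" in meta.columns:
        labels = meta["label"].to_numpy(dtype=object)
        meta = meta.drop(columns=["label"])
    return EpochSet(data=_read_array(directory, sidecar["data"]),
                    eog=_read_array(directory, sidecar["eog"]),
                    labels=labels, trial_meta=meta, sfreq=sidecar["sfreq"],
                    window=(sidecar["window"][0], sidecar["window"][1]),
                    n_rejected=sidecar["n_rejected"],
                    n_skipped=sidecar["n_skipped"])


def save_filter_bank(bank, directory) -> Path:
    """Persist a SpatialFilterBank as binary arrays plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "filters": _write_array(directory / "filters.bin", bank.filters),
        "patterns": _write_array(directory / "patterns.bin", bank.patterns),
        "eigenvalues": _write_array(directory / "eigenvalues.bin",
                                    bank.eigenvalues),
        "class_convention": bank.class_convention,
    }
    (directory / "sidecar.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return directory


def load_filter_bank(directory):
    from .csp import SpatialFilterBank
    directory = Path(directory)
    sidecar = json.loads((directory / "sidecar.json").read_text())
    return SpatialFilterBank(
        filters=_read_array(directory, sidecar["filters"]),
        patterns=_read_array(directory, sidecar["patterns"]),
        eigenvalues=_read_array(directory, sidecar["eigenvalues"]),
        class_convention=sidecar["class_convention"])


def save_features(features, path) -> Path:
    """FeatureMatrix -> CSV (one row per trial, named feature columns)."""
    path = Path(path)
    features.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path
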