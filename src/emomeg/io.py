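"""Readers and writers for epochs, feature matrices, models and ratings.

Epochs persist as ``.npy`` arrays with a JSON sidecar carrying subject,
group, category, sampling rate and onset index; FIF export/import goes
through :mod:`mne` when it is installed.  Feature matrices persist as CSV
(rows = subjects, columns = channel labels) with a JSON sidecar for the
metadata and group labels; the reader re-validates the matrix invariants.
Fitted models round-trip deterministically through JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .lasso import LassoLogisticRegression
from .simulate import EpochSet

RATINGS_COLUMNS = ["subject_id", "group", "picture_id", "category", "valence", "arousal"]


def _epoch_stem(es: EpochSet) -> str:
    return f"{es.subject_id}_{es.category}"


def save_epochs(epochs, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for es in epochs:
        stem = _epoch_stem(es)
        npy = out_dir / f"{stem}.npy"
        np.save(npy, es.data)
        meta = {
            "subject_id": es.subject_id,
            "group": es.group,
            "category": es.category,
            "fs": es.fs,
            "t0_index": es.t0_index,
            "n_trials": int(es.n_trials),
        }
        sidecar = out_dir / f"{stem}.json"
        sidecar.write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
        written += [npy, sidecar]
    return written


def iter_saved_epochs(in_dir):
    """Yield EpochSets from a directory written by :func:`save_epochs`."""
    in_dir = Path(in_dir)
    sidecars = sorted(in_dir.glob("*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no epoch sidecars under {in_dir}")
    for sidecar in sidecars:
        meta = json.loads(sidecar.read_text())
        data = np.load(sidecar.with_suffix(".npy"))
        yield EpochSet(
            subject_id=meta["subject_id"],
            group=int(meta["group"]),
            category=meta["category"],
            data=data,
            fs=float(meta["fs"]),
            t0_index=int(meta["t0_index"]),
        )


def load_epochs(in_dir) -> list[EpochSet]:
    return list(iter_saved_epochs(in_dir))


# ---------------------------------------------------------------- FIF bridge

def epochs_to_fif(es: EpochSet, path) -> Path:
    """Write one EpochSet as an MNE epochs FIF file (requires mne)."""
    import mne

    info = mne.create_info(
        [f"MAG{c:04d}" for c in range(es.n_channels)], es.fs, ch_types="mag"
    )
    info["description"] = json.dumps(
        {"subject_id": es.subject_id, "group": es.group, "category": es.category}
    )
    epochs = mne.EpochsArray(
        np.asarray(es.data, dtype=float),
        info,
        tmin=-es.t0_index / es.fs,
        verbose="error",
    )
    path = Path(path)
    epochs.save(path, overwrite=True, verbose="error")
    return path


def epochs_from_fif(path) -> EpochSet:
    import mne

    epochs = mne.read_epochs(Path(path), preload=True, verbose="error")
    meta = json.loads(epochs.info["description"] or "{}")
    return EpochSet(
        subject_id=meta.get("subject_id", Path(path).stem),
        group=int(meta.get("group", 0)),
        category=meta.get("category", "unknown"),
        data=epochs.get_data(copy=True),
        fs=float(epochs.info["sfreq"]),
        t0_index=int(round(-epochs.tmin * epochs.info["sfreq"])),
    )


# ------------------------------------------------------------ feature tables

def feature_set_stem(category: str, feature_type: str) -> str:
    return f"{category}_{feature_type}"


def save_feature_matrix(fm: FeatureMatrix, out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = feature_set_stem(fm.category, fm.feature_type)
    csv = out_dir / f"{stem}.csv"
    frame = pd.DataFrame(
        fm.values,
        index=pd.Index(fm.subject_ids, name="subject_id"),
        columns=[f"ch{c:03d}" for c in range(fm.n_channels)],
    )
    frame.to_csv(csv, float_format="%.10g")
    sidecar = out_dir / f"{stem}.json"
    sidecar.write_text(
        json.dumps(
            {
                "category": fm.category,
                "feature_type": fm.feature_type,
                "groups": {sid: int(g) for sid, g in zip(fm.subject_ids, fm.y)},
            },
            sort_keys=True,
            indent=1,
        )
        + "\n"
    )
    return [csv, sidecar]


def load_feature_matrix(csv_path) -> FeatureMatrix:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    frame = pd.read_csv(csv_path, index_col="subject_id")
    if frame.isna().any().any():
        bad = frame.stack(future_stack=True)
        bad = bad[bad.isna()]
        loc = bad.index[0]
        raise ValueError(f"missing cell at subject {loc[0]!r}, column {loc[1]!r}")
    missing = [sid for sid in frame.index if sid not in meta["groups"]]
    if missing:
        raise ValueError(f"subjects without group labels in sidecar: {missing}")
    y = np.array([meta["groups"][sid] for sid in frame.index])
    return FeatureMatrix(
        frame.to_numpy(dtype=float),
        list(frame.index),
        y,
        meta["category"],
        meta["feature_type"],
    )


def load_feature_dir(in_dir) -> dict[tuple[str, str], FeatureMatrix]:
    in_dir = Path(in_dir)
    out = {}
    for csv in sorted(in_dir.glob("*.csv")):
        fm = load_feature_matrix(csv)
        out[(fm.category, fm.feature_type)] = fm
    if not out:
        raise FileNotFoundError(f"no feature CSVs under {in_dir}")
    return out


# ------------------------------------------------------------------- models

def model_to_dict(model: LassoLogisticRegression) -> dict:
    return {
        "beta0": model.intercept_,
        "beta": model.coef_.tolist(),
        "lam": model.lam,
        "standardization": {
            "mean": model.mean_.tolist(),
            "scale": model.scale_.tolist(),
        },
        "classes": model.classes_.tolist(),
    }


def save_model(model: LassoLogisticRegression, path, extra: dict | None = None) -> Path:
    payload = model_to_dict(model)
    if extra:
        payload.update(extra)
    path = Path(path)
    path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
    return path


def load_model(path) -> LassoLogisticRegression:
    payload = json.loads(Path(path).read_text())
    model = LassoLogisticRegression(lam=payload["lam"])
    model.coef_ = np.asarray(payload["beta"], dtype=float)
    model.intercept_ = float(payload["beta0"])
    model.mean_ = np.asarray(payload["standardization"]["mean"], dtype=float)
    model.scale_ = np.asarray(payload["standardization"]["scale"], dtype=float)
    model.classes_ = np.asarray(payload["classes"])
    model.n_features_in_ = model.coef_.size
    model.n_iter_ = 0
    return model


# ------------------------------------------------------------------ ratings

def save_ratings(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    table[RATINGS_COLUMNS].to_csv(path, index=False)
    return path


def load_ratings(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in RATINGS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratings table lacks columns {missing}")
    return table
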