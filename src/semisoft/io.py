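"""Dataset CSV dialect and JSON model serialization.

Dataset files are UTF-8 comma-separated tables with a header row and
columns ``batch_id`` (string), ``time`` (hours), ``x_1..x_d`` (numeric
process variables) and optionally ``y`` (the quality variable; empty cells
mark unlabeled rows).  Rows with any missing feature are rejected.

Model files are versioned JSON documents carrying the scaling metadata,
every member's weights, the PLS stacking coefficients and a config echo;
a round-tripped model predicts bit-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SSLDataset
from .elm import ELMMember, NCLELMModel
from .ensemble import Scaler, StackedEnsemble

MODEL_FORMAT_VERSION = 1


def feature_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("x_")]
    if not cols:
        raise ValueError("no feature columns (x_1..x_d) found")
    return cols


def read_dataset(path) -> pd.DataFrame:
    """Read and validate a dataset CSV; unlabeled rows get NaN in ``y``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"batch_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"no data in {path}") from None
    if df.empty:
        raise ValueError(f"no data rows in {path}")
    for col in ("batch_id", "time"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    feats = feature_columns(df)
    for col in ["time", *feats]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(
                f"{path}: non-numeric or missing '{col}' at line {bad[0] + 2}"
            )
        df[col] = vals.astype(float)
    if "y" in df.columns:
        df["y"] = pd.to_numeric(df["y"], errors="coerce")
    return df


def labeled_unlabeled_counts(df: pd.DataFrame) -> tuple[int, int]:
    if "y" not in df.columns:
        return 0, len(df)
    labeled = int(df["y"].notna().sum())
    return labeled, len(df) - labeled


def write_dataset(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def dataframes_to_ssl(
    labeled: pd.DataFrame, unlabeled: pd.DataFrame, validation: pd.DataFrame
) -> SSLDataset:
    """Assemble an SSLDataset from three dataset-dialect frames."""
    feats = feature_columns(labeled)
    for name, df in (("unlabeled", unlabeled), ("validation", validation)):
        if feature_columns(df) != feats:
            raise ValueError(f"{name} set feature columns differ from labeled set")
    for name, df in (("labeled", labeled), ("validation", validation)):
        if "y" not in df.columns or df["y"].isna().any():
            raise ValueError(f"{name} set must have a fully populated y column")
    return SSLDataset(
        X_l=labeled[feats].to_numpy(float),
        y_l=labeled["y"].to_numpy(float),
        X_u=unlabeled[feats].to_numpy(float),
        X_val=validation[feats].to_numpy(float),
        y_val=validation["y"].to_numpy(float),
        y_u_true=None,
        feature_names=feats,
    )


# -- model serialization -----------------------------------------------------

def _member_to_dict(m: ELMMember) -> dict:
    return {
        "input_weights": m.input_weights.tolist(),
        "biases": m.biases.tolist(),
        "output_weights": None if m.output_weights is None else m.output_weights.tolist(),
    }


def _member_from_dict(d: dict) -> ELMMember:
    ow = d["output_weights"]
    return ELMMember(
        input_weights=np.array(d["input_weights"], dtype=float),
        biases=np.array(d["biases"], dtype=float),
        output_weights=None if ow is None else np.array(ow, dtype=float),
    )


def save_model(ensemble: StackedEnsemble, path, meta: dict | None = None) -> None:
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": list(ensemble.feature_names),
        "scaler": None
        if ensemble.scaler is None
        else {
            "mean": ensemble.scaler.mean.tolist(),
            "scale": ensemble.scaler.scale.tolist(),
        },
        "models": [
            {"lam": m.lam, "members": [_member_to_dict(mem) for mem in m.members]}
            for m in ensemble.models
        ],
        "stacking": {
            "coef": ensemble.coef.tolist(),
            "intercept": ensemble.intercept,
            "n_components": ensemble.n_components,
        },
        "meta": meta or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> StackedEnsemble:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {version!r} "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    scaler = None
    if doc["scaler"] is not None:
        scaler = Scaler(
            mean=np.array(doc["scaler"]["mean"], dtype=float),
            scale=np.array(doc["scaler"]["scale"], dtype=float),
        )
    models = tuple(
        NCLELMModel(
            members=tuple(_member_from_dict(d) for d in m["members"]), lam=m["lam"]
        )
        for m in doc["models"]
    )
    return StackedEnsemble(
        models=models,
        coef=np.array(doc["stacking"]["coef"], dtype=float),
        intercept=float(doc["stacking"]["intercept"]),
        n_components=int(doc["stacking"]["n_components"]),
        scaler=scaler,
        feature_names=list(doc["feature_names"]),
    )
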