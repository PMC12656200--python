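"""Feature scaling and dataset splitting for the physiology-prediction ANN.

All variables are mapped into [0, 1] with fixed affine rules rather than
data-driven normalisation, so a trained model transfers between campaigns:

    inputs   voltages / 5, temperature / 50, humidity / 100
    targets  TWSI unchanged, Ig clipped to [0, 1],
             CTD -> (CTD + 20) / 40  (CTD spans -20..+20 degC),
             LAI / 5                 (urban street trees stay below 5)

The input vector order is MQ3, MQ4, MQ8, MQ135, MQ136, MQ137, MQ138, MG811,
temperature, humidity (MQ-7 is logged by the instrument but excluded from
the model inputs); the target order is TWSI, Ig, CTD, LAI.  Rows are split
at random into 70 % training, 15 % validation and 15 % test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

INPUT_ORDER = (
    "MQ3", "MQ4", "MQ8", "MQ135", "MQ136", "MQ137", "MQ138", "MG811",
    "temperature", "humidity",
)
TARGET_ORDER = ("twsi", "ig", "ctd", "lai")

VOLTAGE_DIVISOR = 5.0
TEMPERATURE_DIVISOR = 50.0
HUMIDITY_DIVISOR = 100.0
LAI_DIVISOR = 5.0
CTD_RANGE = (-20.0, 20.0)

SPLIT_FRACTIONS = {"train": 0.70, "val": 0.15, "test": 0.15}
MIN_ROWS = 10


@dataclass
class ScaledDataset:
    """Scaled input/target matrices with per-row split labels."""

    inputs: np.ndarray  # (n, 10) in [0, 1]
    targets: np.ndarray  # (n, 4) in [0, 1]
    split: np.ndarray  # (n,) of {'train','val','test'} ('' before splitting)
    seed: Optional[int] = None
    row_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError("inputs and targets must have matching row counts")
        if self.inputs.shape[1] != len(INPUT_ORDER):
            raise ValueError(f"expected {len(INPUT_ORDER)} input columns")
        if self.targets.shape[1] != len(TARGET_ORDER):
            raise ValueError(f"expected {len(TARGET_ORDER)} target columns")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def subset(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        sel = self.split == label
        return self.inputs[sel], self.targets[sel]


def _clip_warn(value: float, lo: float, hi: float, name: str) -> float:
    if value < lo or value > hi:
        warnings.warn(f"{name}={value} outside [{lo}, {hi}]; clipped", stacklevel=3)
        return min(max(value, lo), hi)
    return value


def scale_inputs(
    voltages: Mapping[str, float], temperature: float, humidity: float
) -> np.ndarray:
    """Scale one sample's sensor readings into the 10-element input vector."""
    missing = [ch for ch in INPUT_ORDER[:8] if ch not in voltages]
    if missing:
        raise KeyError(f"missing gas channels: {missing}")
    vec = [voltages[ch] / VOLTAGE_DIVISOR for ch in INPUT_ORDER[:8]]
    vec.append(temperature / TEMPERATURE_DIVISOR)
    vec.append(humidity / HUMIDITY_DIVISOR)
    if not np.isfinite(vec).all():
        raise ValueError("non-finite input value")
    return np.array(
        [_clip_warn(v, 0.0, 1.0, INPUT_ORDER[i]) for i, v in enumerate(vec)]
    )


def scale_targets(twsi: float, ig: float, ctd: float, lai: float) -> np.ndarray:
    """Scale the four physiological targets into [0, 1]."""
    lo, hi = CTD_RANGE
    ctd = _clip_warn(ctd, lo, hi, "ctd")
    out = np.array(
        [
            _clip_warn(twsi, 0.0, 1.0, "twsi"),
            min(max(ig, 0.0), 1.0),  # Ig above 1 saturates by definition
            (ctd - lo) / (hi - lo),
            _clip_warn(lai / LAI_DIVISOR, 0.0, 1.0, "lai/5"),
        ]
    )
    return out


def unscale_targets(vec: Sequence[float]) -> tuple[float, float, float, float]:
    """Exact inverse of :func:`scale_targets` on the clipped domain."""
    twsi, ig, ctd01, lai01 = (float(v) for v in vec)
    lo, hi = CTD_RANGE
    return twsi, ig, ctd01 * (hi - lo) + lo, lai01 * LAI_DIVISOR


def build_dataset(per_tree: pd.DataFrame) -> ScaledDataset:
    """Assemble a scaled dataset from a fused per-tree table.

    Expects the gas channel columns plus ``temp_C``, ``rh_pct`` and the four
    target columns ``twsi``, ``ig``, ``ctd``, ``lai``.  Rows with any missing
    value are dropped (per-tree means are already aggregates; imputing them
    would double-smooth).
    """
    needed = list(INPUT_ORDER[:8]) + ["temp_C", "rh_pct"] + list(TARGET_ORDER)
    missing = set(needed) - set(per_tree.columns)
    if missing:
        raise ValueError(f"per-tree table missing columns: {sorted(missing)}")
    clean = per_tree.dropna(subset=needed)
    n_drop = len(per_tree) - len(clean)
    if n_drop:
        warnings.warn(f"dropped {n_drop} rows with missing parameters")
    X = np.vstack(
        [
            scale_inputs(
                {ch: row[ch] for ch in INPUT_ORDER[:8]}, row["temp_C"], row["rh_pct"]
            )
            for _, row in clean.iterrows()
        ]
    ) if len(clean) else np.empty((0, len(INPUT_ORDER)))
    Y = np.vstack(
        [
            scale_targets(row["twsi"], row["ig"], row["ctd"], row["lai"])
            for _, row in clean.iterrows()
        ]
    ) if len(clean) else np.empty((0, len(TARGET_ORDER)))
    ids = (
        clean["tree_id"].to_numpy() if "tree_id" in clean.columns else clean.index.to_numpy()
    )
    return ScaledDataset(
        inputs=X, targets=Y, split=np.full(len(clean), "", dtype=object), row_ids=ids
    )


def split_dataset(dataset: ScaledDataset, seed: int) -> ScaledDataset:
    """Randomly label rows train/val/test at 70/15/15 (rounded to rows)."""
    n = len(dataset)
    if n < MIN_ROWS:
        raise ValueError(f"need at least {MIN_ROWS} rows to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(SPLIT_FRACTIONS["train"] * n))
    n_val = int(round(SPLIT_FRACTIONS["val"] * n))
    labels = np.full(n, "test", dtype=object)
    labels[perm[:n_train]] = "train"
    labels[perm[n_train : n_train + n_val]] = "val"
    return ScaledDataset(
        inputs=dataset.inputs,
        targets=dataset.targets,
        split=labels,
        seed=seed,
        row_ids=dataset.row_ids,
    )


def save_dataset(dataset: ScaledDataset, matrix_path: str | Path,
                 manifest_path: Optional[str | Path] = None) -> None:
    """Write the scaled matrices (CSV) and an optional split manifest."""
    df = pd.DataFrame(dataset.inputs, columns=[f"x_{c}" for c in INPUT_ORDER])
    for j, c in enumerate(TARGET_ORDER):
        df[f"y_{c}"] = dataset.targets[:, j]
    df["split"] = dataset.split
    if dataset.row_ids is not None:
        df.insert(0, "row_id", dataset.row_ids)
    df.to_csv(matrix_path, index=False)
    if manifest_path is not None and dataset.row_ids is not None:
        pd.DataFrame({"tree_id": dataset.row_ids, "split": dataset.split}).to_csv(
            manifest_path, index=False
        )


def load_dataset(matrix_path: str | Path) -> ScaledDataset:
    df = pd.read_csv(matrix_path)
    X = df[[f"x_{c}" for c in INPUT_ORDER]].to_numpy()
    Y = df[[f"y_{c}" for c in TARGET_ORDER]].to_numpy()
    split = df["split"].fillna("").to_numpy(dtype=object) if "split" in df else np.full(len(df), "", object)
    ids = df["row_id"].to_numpy() if "row_id" in df.columns else None
    return ScaledDataset(inputs=X, targets=Y, split=split, row_ids=ids)
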