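"""Readers and writers: expression tables, schema/mask archives, checkpoints.

All writers are atomic (temp file in the destination directory, then
rename).  Checkpoints embed a hash of the layer schema so that a model can
never be silently applied to masks or data laid out differently.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import os
import tempfile
import zipfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import ExpressionDataset, NetworkParameters
from .ontology import LayerSchema


def _atomic_write_bytes(path: Path, payload: bytes) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def schema_hash(schema: LayerSchema) -> str:
    return hashlib.sha256(schema.to_json().encode()).hexdigest()


# ---------------------------------------------------------------------------
# expression tables

def read_expression(
    path,
    label_column: str = "label",
    labels_path=None,
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a samples x probes table (header row = probe IDs).

    The label may live in ``label_column`` of the same table or in a
    separate single-column file.  Class labels are mapped to indices
    0..K-1 in sorted label order.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if labels_path is not None:
        labels = pd.read_csv(labels_path, header=None).iloc[:, 0].to_numpy()
        if len(labels) != len(df):
            raise ValueError(f"{len(labels)} labels for {len(df)} samples")
    elif label_column in df.columns:
        labels = df.pop(label_column).to_numpy()
    else:
        raise ValueError(f"no label column {label_column!r} and no labels file")
    classes = sorted(pd.unique(labels).tolist())
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_to_idx[v] for v in labels])
    return ExpressionDataset(
        X=df.to_numpy(dtype=float),
        y=y,
        probe_ids=tuple(str(c) for c in df.columns),
        class_names=tuple(str(c) for c in classes),
    )


def write_expression(dataset: ExpressionDataset, path, label_column: str = "label",
                     sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.DataFrame(dataset.X, columns=list(dataset.probe_ids))
    names = dataset.class_names or tuple(range(dataset.n_classes))
    df[label_column] = [names[i] for i in dataset.y]
    df.index.name = "sample"
    buf = _io.StringIO()
    # %.17g round-trips doubles exactly
    df.to_csv(buf, sep=sep, float_format="%.17g")
    _atomic_write_bytes(Path(path), buf.getvalue().encode())


# ---------------------------------------------------------------------------
# schema + masks archive

def save_schema(path, schema: LayerSchema, masks: Sequence[np.ndarray]) -> None:
    """One .npz archive: JSON manifest plus the dense mask payloads."""
    buf = _io.BytesIO()
    arrays = {f"mask_{i}": m for i, m in enumerate(masks)}
    np.savez_compressed(buf, manifest=np.frombuffer(schema.to_json().encode(), dtype=np.uint8),
                        n_masks=np.array(len(masks)), **arrays)
    _atomic_write_bytes(Path(path), buf.getvalue())


def load_schema(path) -> tuple[LayerSchema, list[np.ndarray]]:
    with np.load(path) as z:
        schema = LayerSchema.from_json(bytes(z["manifest"]).decode())
        masks = [z[f"mask_{i}"] for i in range(int(z["n_masks"]))]
    return schema, masks


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(
    path,
    params: NetworkParameters,
    schema: LayerSchema,
    config: dict,
    standardization: dict | None = None,
) -> None:
    """Single-archive checkpoint: parameters, schema (and its hash),
    training config and standardization statistics."""
    meta = {
        "schema_hash": schema_hash(schema),
        "config": config,
        "n_layers": len(params.weights),
    }
    arrays = {}
    for i, (w, b) in enumerate(zip(params.weights, params.biases)):
        arrays[f"W_{i}"] = w
        arrays[f"b_{i}"] = b
    if standardization:
        arrays["std_mean"] = np.asarray(standardization["mean"])
        arrays["std_sd"] = np.asarray(standardization["sd"])
    buf = _io.BytesIO()
    np.savez_compressed(
        buf,
        meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
        manifest=np.frombuffer(schema.to_json().encode(), dtype=np.uint8),
        **arrays,
    )
    _atomic_write_bytes(Path(path), buf.getvalue())


def load_checkpoint(path, expect_schema: LayerSchema | None = None):
    """Load a checkpoint; refuses to proceed when the stored schema hash
    does not match ``expect_schema``.  Returns (params, schema, meta,
    standardization)."""
    try:
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            schema = LayerSchema.from_json(bytes(z["manifest"]).decode())
            n = int(meta["n_layers"])
            weights = [z[f"W_{i}"] for i in range(n)]
            biases = [z[f"b_{i}"] for i in range(n)]
            standardization = None
            if "std_mean" in z:
                standardization = {"mean": z["std_mean"], "sd": z["std_sd"]}
    except (OSError, EOFError, ValueError, KeyError, json.JSONDecodeError,
            zipfile.BadZipFile) as exc:
        raise ValueError(f"unreadable or truncated checkpoint {path}: {exc}") from exc
    if expect_schema is not None and schema_hash(expect_schema) != meta["schema_hash"]:
        raise ValueError(
            "checkpoint schema hash does not match the provided schema; "
            "refusing inference with mismatched masks")
    return NetworkParameters(weights, biases), schema, meta, standardization


def write_json(path, payload) -> None:
    _atomic_write_bytes(Path(path), (json.dumps(payload, indent=2, sort_keys=True) + "\n").encode())


def write_tsv(path, df: pd.DataFrame) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    _atomic_write_bytes(Path(path), buf.getvalue().encode())
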