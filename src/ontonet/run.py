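"""Run orchestration: configuration, end-to-end pipeline, alpha sweeps."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as onio
from .interpret import connection_norms
from .model import (ExpressionDataset, TrainingConfig, evaluate, train)
from .ontology import (build_layer_schema, parse_obo, propagate_annotations,
                       read_annotations)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a training run needs; serialized next to every output."""

    obo: str | None = None
    annotations: str | None = None
    expression: str | None = None
    labels: str | None = None
    out_dir: str | None = None
    levels_band: tuple[int, ...] = (6, 5, 4, 3, 2, 1)
    namespace: str = "biological_process"
    retained_relations: tuple[str, ...] = ("is_a",)
    alpha: float = 1e-2
    regularizer: str = "go"
    optimizer: str = "adam"
    learning_rate: float = 0.001
    momentum: float = 0.9
    dropout: float = 0.6
    epochs: int = 600
    batch_size: int = 128
    test_fraction: float = 0.2
    standardize: str = "train"    # train | global | none
    seed: int = 0

    def training_config(self, seed: int | None = None) -> TrainingConfig:
        return TrainingConfig(
            alpha=self.alpha, regularizer=self.regularizer,
            optimizer=self.optimizer, learning_rate=self.learning_rate,
            momentum=self.momentum, dropout_rate=self.dropout,
            epochs=self.epochs, batch_size=self.batch_size,
            seed=self.seed if seed is None else seed,
        )

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def build_schema_from_files(config: RunConfig, probe_order: Sequence[str], n_classes: int):
    """OBO + annotations -> (schema, masks) per the run configuration."""
    dag = parse_obo(config.obo, retained_relations=config.retained_relations,
                    namespace=config.namespace)
    direct = read_annotations(config.annotations)
    amap = propagate_annotations(dag, direct, all_probes=probe_order)
    return build_layer_schema(dag, config.levels_band, amap, probe_order, n_classes)


def fit_pipeline(config: RunConfig, dataset: ExpressionDataset, schema, masks):
    """Split, standardize, train, evaluate.  Returns a result dict."""
    train_set, test_set = dataset.split(
        test_fraction=config.test_fraction, seed=config.seed,
        standardize=config.standardize)
    params, log = train(train_set, schema, masks, config.training_config())
    metrics = evaluate(params, test_set.X, test_set.y)
    return {
        "params": params, "log": log, "metrics": metrics,
        "train_set": train_set, "test_set": test_set,
    }


def run_alpha_sweep(
    dataset: ExpressionDataset,
    schema,
    masks,
    alphas: Sequence[float],
    n_seeds: int = 1,
    regularizers: Sequence[str] = ("go",),
    base_config: RunConfig | None = None,
) -> pd.DataFrame:
    """Train a model per (regularizer, alpha, seed) and tabulate accuracy
    and GO/noGO norm diagnostics.

    Individual failures are recorded in the ``error`` column and the sweep
    continues.  The table is tidy: one row per trained model.
    """
    if len(alphas) == 0:
        raise ValueError("alphas must be non-empty")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    base = base_config or RunConfig()
    rows = []
    for reg in regularizers:
        for alpha in alphas:
            for seed in range(n_seeds):
                cfg = replace(base, regularizer=reg, alpha=float(alpha), seed=seed)
                row = {"regularizer": reg, "alpha": float(alpha), "seed": seed}
                try:
                    res = fit_pipeline(cfg, dataset, schema, masks)
                    go, nogo, ratio = connection_norms(res["params"], masks)
                    row.update(accuracy=res["metrics"]["accuracy"],
                               go_norm=go, nogo_norm=nogo, ratio=ratio, error="")
                except Exception as exc:  # keep sweeping, record the failure
                    logger.exception("sweep run failed: %s", row)
                    row.update(accuracy=np.nan, go_norm=np.nan,
                               nogo_norm=np.nan, ratio=np.nan, error=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)
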