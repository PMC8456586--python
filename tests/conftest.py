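import io

import numpy as np
import pytest

from ontonet import (ExpressionDataset, LayerSchema, RunConfig, build_layer_schema,
                     propagate_annotations)
from ontonet.run import fit_pipeline
from ontonet.synthetic import SyntheticSpec, generate_bundle

CHAIN_OBO = """format-version: 1.2
ontology: test

[Term]
id: T:0000001
name: root process
namespace: biological_process

[Term]
id: T:0000002
name: middle process
namespace: biological_process
is_a: T:0000001

[Term]
id: T:0000003
name: leaf process
namespace: biological_process
is_a: T:0000002
relationship: part_of T:0000001
"""


@pytest.fixture
def chain_obo(tmp_path):
    path = tmp_path / "chain.obo"
    path.write_text(CHAIN_OBO)
    return path


def make_schema(n_probes: int, layer_sizes: tuple[int, ...], n_classes: int = 2,
                rng: np.random.Generator | None = None):
    """A free-standing schema + random 0/1 masks for model-level tests."""
    rng = rng or np.random.default_rng(0)
    layer_terms = tuple(
        tuple(f"L{l}:{i:03d}" for i in range(n)) for l, n in enumerate(layer_sizes, 1))
    schema = LayerSchema(
        levels=tuple(range(len(layer_sizes), 0, -1)),
        layer_terms=layer_terms,
        probe_order=tuple(f"P{j:04d}" for j in range(n_probes)),
        n_classes=n_classes,
    )
    sizes = [n_probes, *layer_sizes]
    masks = [(rng.random((a, b)) < 0.3).astype(float)
             for a, b in zip(sizes[:-1], sizes[1:])]
    return schema, masks


@pytest.fixture(scope="session")
def bench():
    """The default synthetic benchmark: bundle, schema, masks, dataset."""
    bundle = generate_bundle(SyntheticSpec(seed=0))
    amap = propagate_annotations(bundle.dag, bundle.direct_annotations,
                                 all_probes=bundle.probe_order)
    schema, masks = build_layer_schema(bundle.dag, (6, 5, 4, 3, 2, 1), amap,
                                       bundle.probe_order, 2)
    dataset = ExpressionDataset(bundle.X, bundle.y, tuple(bundle.probe_order))
    return {"bundle": bundle, "amap": amap, "schema": schema,
            "masks": masks, "dataset": dataset}


@pytest.fixture(scope="session")
def trained_go_model(bench):
    """GO-regularized model at alpha=1e-2 on the benchmark (no dropout: the
    scaled-down layers are too narrow for the real-scale 0.6 rate)."""
    cfg = RunConfig(alpha=1e-2, regularizer="go", dropout=0.0, epochs=600, seed=0)
    res = fit_pipeline(cfg, bench["dataset"], bench["schema"], bench["masks"])
    return res
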