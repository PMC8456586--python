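"""Interpretation of a trained ontology-constrained network.

Four families of diagnostics:

* layer-wise relevance propagation (epsilon rule) — how much of the output
  logit flows through each neuron;
* GO/noGO connection-weight diagnostics — mean absolute weights over the two
  connection classes, their ratio, and per-layer sorted weight tables;
* the target-mask procedure — does a first-layer neuron respond more to the
  probes of its own ontology term than to any other term's probe set?
* activation-profile clustering and ranked term reports over sample cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .model import NetworkParameters, forward, predict_proba
from .ontology import LayerSchema

EPSILON_DEFAULT = 1e-7   # the epsilon of the relevance formula itself
EPSILON_REPORT = 0.1     # stabilized epsilon for cohort-level reports (see docs)


# ---------------------------------------------------------------------------
# layer-wise relevance propagation

def lrp_relevance(
    params: NetworkParameters,
    X: np.ndarray,
    epsilon: float = EPSILON_DEFAULT,
    explain_class: int | None = None,
) -> list[np.ndarray]:
    """Epsilon-rule relevance for every sample in ``X``.

    The relevance of the explained output neuron is seeded with its
    pre-activation logit z^(L): the single logit for a binary head, the
    predicted class's logit for a multiclass head (other outputs seeded 0).
    ``explain_class`` explains a fixed class instead of the prediction; for
    a binary head, class 0's logit in the single-logit parameterization is
    -z^(L), so relevance is then positive for neurons supporting class 0.
    Backward through each layer,

        R_i = sum_j  a_i w_ij / (sum_k a_k w_kj + eps_j)  *  R_j

    with eps_j carrying the sign of the denominator.  Biases are not part of
    the denominator, so relevance is conserved exactly only on bias-free
    networks.

    Returns one (n_samples, N_l) array per layer, from the input layer
    (index 0) to the output layer (index L+1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    acts, probs = forward(params, X)
    z_out = acts[-1] @ params.weights[-1] + params.biases[-1]

    r_out = np.zeros_like(z_out)
    if z_out.shape[1] == 1:
        sign = -1.0 if explain_class == 0 else 1.0
        r_out[:, 0] = sign * z_out[:, 0]
    else:
        if explain_class is None:
            target = probs.argmax(axis=1)
        else:
            target = np.full(len(z_out), int(explain_class))
        r_out[np.arange(len(target)), target] = z_out[np.arange(len(target)), target]

    relevances = [r_out]
    r_upper = r_out
    for l in range(len(params.weights) - 1, -1, -1):
        a = acts[l]                     # (n, N_l)
        w = params.weights[l]           # (N_l, N_{l+1})
        denom = a @ w                   # sum_k a_k w_kj, biases excluded
        denom = denom + epsilon * np.where(denom >= 0, 1.0, -1.0)
        ratio = r_upper / denom         # (n, N_{l+1})
        r = a * (ratio @ w.T)
        relevances.append(r)
        r_upper = r
    relevances.reverse()
    return relevances


def lrp_relevance_bruteforce(
    params: NetworkParameters,
    x: np.ndarray,
    epsilon: float = EPSILON_DEFAULT,
) -> list[np.ndarray]:
    """Literal triple-loop transcription of the epsilon rule for one sample.

    Independent oracle for :func:`lrp_relevance`; O(N^2) per layer and only
    meant for small networks in tests.
    """
    x = np.asarray(x, dtype=float).ravel()
    acts, probs = forward(params, x[None, :])
    acts = [a[0] for a in acts]
    z_out = acts[-1] @ params.weights[-1] + params.biases[-1]

    r_upper = np.zeros_like(z_out)
    if z_out.shape[0] == 1:
        r_upper[0] = z_out[0]
    else:
        k = int(probs[0].argmax())
        r_upper[k] = z_out[k]

    out = [r_upper]
    for l in range(len(params.weights) - 1, -1, -1):
        a, w = acts[l], params.weights[l]
        r = np.zeros(w.shape[0])
        for i in range(w.shape[0]):
            s = 0.0
            for j in range(w.shape[1]):
                denom = 0.0
                for k in range(w.shape[0]):
                    denom += a[k] * w[k, j]
                denom += epsilon if denom >= 0 else -epsilon
                s += a[i] * w[i, j] / denom * r_upper[j]
            r[i] = s
        out.append(r)
        r_upper = r
    out.reverse()
    return out


# ---------------------------------------------------------------------------
# connection-weight diagnostics

def connection_norms(
    params: NetworkParameters, masks: Sequence[np.ndarray]
) -> tuple[float, float, float]:
    """Mean absolute weight of GO and noGO connections, and their ratio.

    Each hidden layer contributes its own mean absolute GO (resp. noGO)
    weight, and the layer means are averaged with equal weight (1/L); the
    output layer, whose mask is all ones, is excluded.  Per-layer
    normalization keeps the diagnostic unbiased when the GO fraction and
    the natural weight scale differ across layers: at random initialization
    the ratio is ~1 by construction.  A zero noGO norm yields an infinite
    ratio sentinel.
    """
    if len(masks) != params.n_hidden:
        raise ValueError(f"{len(masks)} masks for {params.n_hidden} hidden layers")
    go_layers, nogo_layers = [], []
    for w, c in zip(params.weights[:-1], masks):
        if w.shape != c.shape:
            raise ValueError(f"mask shape {c.shape} != weight shape {w.shape}")
        n_go = int(c.sum())
        n_nogo = c.size - n_go
        if n_go == 0 or n_nogo == 0:
            raise ValueError("every hidden layer needs both GO and noGO connections")
        aw = np.abs(w)
        go_layers.append(float((aw * c).sum()) / n_go)
        nogo_layers.append(float((aw * (1.0 - c)).sum()) / n_nogo)
    go_norm = float(np.mean(go_layers))
    nogo_norm = float(np.mean(nogo_layers))
    ratio = np.inf if nogo_norm == 0 else go_norm / nogo_norm
    return go_norm, nogo_norm, ratio


def sort_connection_weights(
    params: NetworkParameters, masks: Sequence[np.ndarray], layer: int
) -> pd.DataFrame:
    """All incoming connections of a hidden layer sorted by |weight|.

    ``layer`` is 1-based.  Ties are broken by (row, column) index, so the
    table is deterministic.  Columns: rank, row, col, abs_weight, is_go.
    """
    if not 1 <= layer <= params.n_hidden:
        raise ValueError(f"layer must be in 1..{params.n_hidden}")
    w = params.weights[layer - 1]
    c = masks[layer - 1]
    rows, cols = np.unravel_index(np.arange(w.size), w.shape)
    df = pd.DataFrame({
        "row": rows,
        "col": cols,
        "abs_weight": np.abs(w).ravel(),
        "is_go": c.ravel().astype(bool),
    })
    df = df.sort_values(["abs_weight", "row", "col"],
                        ascending=[False, True, True], kind="mergesort")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# target-mask procedure

def ranks_decreasing(values: np.ndarray) -> np.ndarray:
    """Rank positions (1 = largest) with ties broken by index."""
    values = np.asarray(values, dtype=float)
    order = np.lexsort((np.arange(len(values)), -values))
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def target_mask_ranks_from_means(mean_activations: np.ndarray) -> np.ndarray:
    """Target-mask rank of each neuron from its mean masked activations.

    ``mean_activations[i, p]`` is the mean activation of neuron *i* under
    mask *p*; a neuron's own mask shares its index.  The rank of neuron *i*
    is the position of entry (i, i) when row *i* is ordered decreasingly;
    it is NULL (represented as -1) when the own-mask activation is zero.
    """
    a = np.asarray(mean_activations, dtype=float)
    n = a.shape[0]
    out = np.empty(n, dtype=int)
    for i in range(n):
        out[i] = -1 if a[i, i] == 0 else ranks_decreasing(a[i])[i]
    return out


@dataclass
class MaskRankReport:
    """Per first-layer-neuron outcome of the target-mask validation."""

    table: pd.DataFrame            # term, target_mask_rank (-1 = NULL), lrp_rank
    mean_masked_activations: np.ndarray   # (N_1, N_1): neuron x mask
    mean_relevance: np.ndarray            # (N_1,)


def target_mask_rank(
    params: NetworkParameters,
    schema: LayerSchema,
    masks: Sequence[np.ndarray],
    X: np.ndarray,
    epsilon: float = EPSILON_REPORT,
    allow_duplicate_masks: bool = False,
) -> MaskRankReport:
    """Validate that first-layer neurons embody their ontology terms.

    Each first-layer term defines a mask: standardized inputs with every
    probe outside the term's propagated probe set zeroed (zero being the
    training mean after standardization).  For every neuron *i* and mask
    *p* the first-layer activation is averaged over the samples; the rank of
    a neuron's own mask within the decreasing ordering of its row is its
    target-mask rank (NULL, coded -1, when the own-mask activation is 0).
    LRP ranks order the neurons by their mean relevance.

    Two terms with identical probe sets make masks indistinguishable and
    raise, unless ``allow_duplicate_masks`` is set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    c1 = masks[0]
    n1 = c1.shape[1]

    seen: dict[tuple, int] = {}
    for p in range(n1):
        key = tuple(np.flatnonzero(c1[:, p]))
        if key in seen and not allow_duplicate_masks:
            raise ValueError(
                f"terms {schema.layer_terms[0][seen[key]]} and "
                f"{schema.layer_terms[0][p]} have identical probe sets")
        seen.setdefault(key, p)

    a_bar = np.empty((n1, n1))
    for p in range(n1):
        acts, _ = forward(params, X * c1[:, p])
        a_bar[:, p] = acts[1].mean(axis=0)

    mask_ranks = target_mask_ranks_from_means(a_bar)

    rel = lrp_relevance(params, X, epsilon=epsilon)
    r_bar = rel[1].mean(axis=0)
    lrp_ranks = ranks_decreasing(r_bar)

    table = pd.DataFrame({
        "neuron": np.arange(n1),
        "term": schema.layer_terms[0],
        "target_mask_rank": mask_ranks,
        "lrp_rank": lrp_ranks,
        "own_mask_activation": np.diag(a_bar),
        "mean_relevance": r_bar,
    })
    return MaskRankReport(table=table, mean_masked_activations=a_bar,
                          mean_relevance=r_bar)


# ---------------------------------------------------------------------------
# activation clustering

def activation_profiles(params: NetworkParameters, X: np.ndarray) -> list[np.ndarray]:
    """Per-layer (n_samples, N_l) ReLU activation matrices (hidden layers only)."""
    acts, _ = forward(params, X)
    return acts[1:]


def cluster_activation_profiles(
    activations: np.ndarray,
    n_clusters: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Average-linkage hierarchical clustering on euclidean distances.

    Returns the scipy linkage matrix and, when ``n_clusters`` is given, flat
    cluster labels from cutting the tree (maxclust criterion).
    """
    A = np.atleast_2d(np.asarray(activations, dtype=float))
    if A.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    Z = linkage(A, method="average", metric="euclidean")
    labels = None
    if n_clusters is not None:
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, labels


def linkage_to_newick(Z: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch lengths."""
    from scipy.cluster.hierarchy import to_tree

    tree = to_tree(Z)

    def recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# ranked term reports

def top_terms_report(
    relevances: Sequence[np.ndarray],
    schema: LayerSchema,
    sample_subset: Sequence[int] | None = None,
    k: int = 5,
) -> dict[int, pd.DataFrame]:
    """Top-k most relevant terms per hidden layer for a cohort of samples.

    ``relevances`` is the output of :func:`lrp_relevance`; the mean
    relevance of each hidden-layer neuron over ``sample_subset`` (all
    samples when None) is ranked decreasingly, ties broken by term ID.
    Returns {layer (1-based): DataFrame(term, name, mean_relevance)}.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    reports: dict[int, pd.DataFrame] = {}
    for l in range(1, schema.n_hidden + 1):
        r = relevances[l]
        if sample_subset is not None:
            idx = np.asarray(sample_subset)
            if idx.size == 0:
                raise ValueError("sample_subset must be non-empty")
            r = r[idx]
        mean_r = r.mean(axis=0)
        terms = schema.layer_terms[l - 1]
        if k > len(terms):
            warnings.warn(
                f"k={k} exceeds the {len(terms)} neurons of layer {l}; truncating")
        df = pd.DataFrame({
            "term": terms,
            "name": [schema.term_names.get(t, t) for t in terms],
            "mean_relevance": mean_r,
        })
        df = df.sort_values(["mean_relevance", "term"],
                            ascending=[False, True], kind="mergesort")
        reports[l] = df.head(min(k, len(terms))).reset_index(drop=True)
    return reports
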