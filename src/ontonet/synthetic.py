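"""Synthetic ontologies, annotations, and expression with planted structure.

The generator emulates the three biological inputs the pipeline consumes:

* a layered ontology DAG (every non-root term has at least one parent one
  level up, plus optional extra same-band parents and skip-level parents);
* probe annotations to the deepest-level terms, with realistic set sizes
  (median around 8 probes per term) and a configurable fraction of probes
  with no annotation at all, mirroring the roughly one third of microarray
  probes that lack any ontology annotation;
* an expression matrix whose class signal is injected through the probe
  sets of chosen "signal" terms, so that recovery of those terms by the
  interpretation stack can be scored against ground truth.

Defaults describe the standard benchmark used throughout the test-suite:
a 6-level DAG, 300 probes, 600 samples with a 66/34 class split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ontology import OntologyDAG, parse_obo

ROOT_ID = "ST:0000000"


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    ``terms_per_level`` runs from level 1 (just below the root) down to the
    deepest level; the default profile widens toward the middle and deep
    levels the way real ontology level sizes do, so no hidden layer is a
    degenerate bottleneck.  ``class_proportions`` mirrors a cancer-prevalence-style
    66/34 imbalance; ``unannotated_probe_fraction`` of probes receive no
    annotation.  ``n_signal_terms`` deepest-level terms carry the class
    signal: their probes are mean-shifted by ``effect_size`` (in units of
    the noise sd) in samples of the class assigned to the term.
    """

    n_levels: int = 6
    terms_per_level: tuple[int, ...] = (6, 9, 12, 14, 16, 20)
    extra_parent_density: float = 0.25
    skip_edge_fraction: float = 0.1
    n_probes: int = 300
    probes_per_term_median: int = 8
    probes_per_term_sigma: float = 0.6
    unannotated_probe_fraction: float = 0.33
    n_samples: int = 600
    class_proportions: tuple[float, ...] = (0.66, 0.34)
    n_signal_terms: int = 2
    signal_terms: tuple[str, ...] | None = None
    effect_size: float = 2.0
    noise_sd: float = 1.0
    signal_in_unannotated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.terms_per_level) != self.n_levels:
            raise ValueError("terms_per_level must have n_levels entries")
        for frac in (self.extra_parent_density, self.skip_edge_fraction,
                     self.unannotated_probe_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if self.n_signal_terms < 1 and self.signal_terms is None:
            raise ValueError("at least one signal term is required")


def _term_id(level: int, i: int) -> str:
    return f"ST:{level:02d}{i + 1:05d}"


def generate_dag(spec: SyntheticSpec) -> tuple[str, dict[str, int]]:
    """Generate a layered DAG as OBO text plus ground-truth levels.

    Every term at level h gets >= 1 parent at level h-1, a
    density-controlled number of extra parents at level h-1, and with
    probability ``skip_edge_fraction`` one extra parent more than one level
    up.  Because each term always has a parent exactly one level up, and
    skip parents are strictly shallower, the longest root-to-term path
    length equals the construction level by induction.
    """
    rng = np.random.default_rng(spec.seed)
    levels: dict[str, int] = {ROOT_ID: 0}
    tiers: list[list[str]] = [[ROOT_ID]]
    edges: list[tuple[str, str]] = []

    for h in range(1, spec.n_levels + 1):
        tier = [_term_id(h, i) for i in range(spec.terms_per_level[h - 1])]
        above = tiers[h - 1]
        for t in tier:
            levels[t] = h
            parents = {above[rng.integers(len(above))]}
            for cand in above:
                if cand not in parents and rng.random() < spec.extra_parent_density:
                    parents.add(cand)
            if h >= 2 and rng.random() < spec.skip_edge_fraction:
                skip_level = int(rng.integers(0, h - 1))  # strictly above h-1
                skip_tier = tiers[skip_level]
                parents.add(skip_tier[rng.integers(len(skip_tier))])
            edges.extend((t, p) for p in sorted(parents))
        tiers.append(tier)

    stanzas = ["format-version: 1.2", "ontology: synthetic", ""]
    for term in sorted(levels):
        stanzas.append("[Term]")
        stanzas.append(f"id: {term}")
        name = "synthetic root" if term == ROOT_ID else f"synthetic term {term}"
        stanzas.append(f"name: {name}")
        stanzas.append("namespace: biological_process")
        for child, parent in edges:
            if child == term:
                stanzas.append(f"is_a: {parent}")
        stanzas.append("")
    return "\n".join(stanzas), levels


def write_obo(text: str, path) -> None:
    Path(path).write_text(text)


def parse_generated(obo_text: str, tmp_path=None) -> OntologyDAG:
    """Parse generated OBO text through the standard reader."""
    import io

    return parse_obo(io.StringIO(obo_text))


def _probe_ids(n: int) -> list[str]:
    return [f"PRB{i + 1:05d}_at" for i in range(n)]


def generate_annotations(
    spec: SyntheticSpec, levels: dict[str, int]
) -> tuple[dict[str, set[str]], list[str]]:
    """Annotate probes to the deepest-level terms.

    Set sizes are drawn from a lognormal around ``probes_per_term_median``
    and the annotated probe pool is dealt out in disjoint blocks (deepest
    sibling terms of a real ontology share few probes); leftover pool
    probes are appended to random terms so every annotated probe carries at
    least one term.  An ``unannotated_probe_fraction`` of probes receive
    nothing.  No two terms may share an identical probe set; a pool too
    small to give every term a distinct non-empty block raises.  Returns
    (probe -> terms, full probe order).
    """
    rng = np.random.default_rng(spec.seed + 1)
    probes = _probe_ids(spec.n_probes)
    n_unannot = int(round(spec.unannotated_probe_fraction * spec.n_probes))
    pool = list(probes[: spec.n_probes - n_unannot])  # annotated pool; rest stay bare
    deepest = sorted(t for t, h in levels.items() if h == spec.n_levels)

    if len(pool) < len(deepest):
        raise ValueError(
            f"cannot build {len(deepest)} distinct probe sets from {len(pool)} probes")

    sizes = {}
    for t in deepest:
        sizes[t] = max(1, int(round(rng.lognormal(
            math.log(spec.probes_per_term_median), spec.probes_per_term_sigma))))
    # shrink proportionally if the pool cannot host disjoint blocks
    total = sum(sizes.values())
    if total > len(pool):
        scale = len(pool) / total
        sizes = {t: max(1, int(s * scale)) for t, s in sizes.items()}

    shuffled = list(pool)
    rng.shuffle(shuffled)
    term_probes: dict[str, set[str]] = {}
    cursor = 0
    for t in deepest:
        term_probes[t] = set(shuffled[cursor:cursor + sizes[t]])
        cursor += sizes[t]
    for p in shuffled[cursor:]:  # leftovers keep the whole pool annotated
        term_probes[deepest[rng.integers(len(deepest))]].add(p)

    seen: set[frozenset] = set()
    for t, ps in term_probes.items():
        key = frozenset(ps)
        if key in seen:
            raise ValueError(f"term {t} duplicates another term's probe set")
        seen.add(key)

    direct: dict[str, set[str]] = {}
    for t, ps in term_probes.items():
        for p in ps:
            direct.setdefault(p, set()).add(t)
    return direct, probes


def annotations_to_tsv(direct: dict[str, set[str]]) -> str:
    lines = [f"{p}\t{t}" for p in sorted(direct) for t in sorted(direct[p])]
    return "\n".join(lines) + "\n"


@dataclass
class ExpressionGroundTruth:
    signal_terms: dict[str, int]          # term -> class it marks
    signal_probes: dict[str, set[str]]    # term -> probes carrying the shift


def generate_expression(
    spec: SyntheticSpec,
    levels: dict[str, int],
    direct: dict[str, set[str]],
    probe_order: list[str],
) -> tuple[np.ndarray, np.ndarray, ExpressionGroundTruth]:
    """Expression matrix with a class signal planted through signal terms.

    Class labels follow ``class_proportions`` exactly (up to rounding);
    every probe gets iid Gaussian noise, and each signal term's probes are
    shifted by ``effect_size`` in the samples of the term's class.  Signal
    terms cycle through the classes starting from class 1 (the "positive"
    class of a binary problem), so each class has an informative term when
    there are at least as many signal terms as classes.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n, k = spec.n_samples, len(spec.class_proportions)

    counts = [int(round(p * n)) for p in spec.class_proportions]
    counts[-1] = n - sum(counts[:-1])
    y = np.repeat(np.arange(k), counts)
    rng.shuffle(y)

    term_probes: dict[str, set[str]] = {}
    for p, terms in direct.items():
        for t in terms:
            term_probes.setdefault(t, set()).add(p)
    deepest = sorted(t for t, h in levels.items() if h == spec.n_levels)

    if spec.signal_terms is not None:
        chosen = list(spec.signal_terms)
        missing = [t for t in chosen if t not in deepest]
        if missing:
            raise ValueError(f"signal terms not at the deepest level: {missing}")
    else:
        annotated = [t for t in deepest if term_probes.get(t)]
        order = rng.permutation(len(annotated))
        chosen = [annotated[i] for i in order[: spec.n_signal_terms]]

    X = rng.normal(0.0, spec.noise_sd, size=(n, len(probe_order)))
    col = {p: j for j, p in enumerate(probe_order)}
    signal_terms: dict[str, int] = {}
    signal_probes: dict[str, set[str]] = {}
    unannotated = [p for p in probe_order if p not in direct]
    for rank, t in enumerate(chosen):
        cls = (rank + 1) % k
        signal_terms[t] = cls
        if spec.signal_in_unannotated:
            take = min(len(term_probes.get(t, set())) or spec.probes_per_term_median,
                       len(unannotated))
            probes = set(rng.choice(unannotated, size=take, replace=False))
        else:
            probes = set(term_probes.get(t, set()))
        signal_probes[t] = probes
        cols = [col[p] for p in probes]
        X[np.ix_(y == cls, cols)] += spec.effect_size

    return X, y, ExpressionGroundTruth(signal_terms, signal_probes)


@dataclass
class SyntheticBundle:
    """Everything one run of the generator produced."""

    spec: SyntheticSpec
    obo_text: str
    levels: dict[str, int]
    direct_annotations: dict[str, set[str]]
    probe_order: list[str]
    X: np.ndarray
    y: np.ndarray
    truth: ExpressionGroundTruth
    dag: OntologyDAG = field(repr=False, default=None)


def generate_bundle(spec: SyntheticSpec | None = None, seed: int | None = None) -> SyntheticBundle:
    """Run the full generator: DAG, annotations, expression."""
    spec = spec or SyntheticSpec()
    if seed is not None:
        from dataclasses import replace

        spec = replace(spec, seed=seed)
    obo_text, levels = generate_dag(spec)
    direct, probe_order = generate_annotations(spec, levels)
    X, y, truth = generate_expression(spec, levels, direct, probe_order)
    dag = parse_generated(obo_text)
    return SyntheticBundle(spec, obo_text, levels, direct, probe_order, X, y, truth, dag=dag)
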