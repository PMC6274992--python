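"""Synthetic staged cohorts with planted rank-order deregulation.

The generator emulates the structure of a multi-stage tumor expression
study with a shared normal-control cohort: every gene has a fixed
baseline (log-scale) expression defining a canonical within-set
ordering; samples are the baseline plus independent Gaussian jitter; in
*case* samples a planted gene set is deregulated by permuting the values
of a fraction pi of its member genes among themselves, per sample. The
GSR index responds only to ordering, so this permutation is the minimal
faithful perturbation: pi = 0 leaves a set null, pi = 1 fully scrambles
it, and stage-increasing pi produces progressive deregulation.

A companion ontology generator emits a random DAG with two designated
"immune" ancestor terms, one gene set per term, and a consistent
name-based term mapping — everything the downstream immunofunctionome
extraction needs, in the exact formats the readers consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from gsrpipe.go_dag import GoDag, TermMapping, normalize_term_name
from gsrpipe.io_formats import ExpressionMatrix, GeneSet, GeneSetCollection

STAGES = ("stageI", "stageII", "stageIII", "stageIV")


@dataclass
class SyntheticConfig:
    """Study-shaped simulation parameters.

    Defaults are a scaled-down analogue of a multi-stage carcinoma
    cohort: 200 gene sets over a 1000-gene universe, 40 cases per stage
    vs 40 controls, 10 sets deregulated at constant severity across all
    stages (``n_common``, pi = 0.5) and 10 with stage-increasing severity
    (``n_progressive``, pi rising 0.4 -> 1.0: the severities bracket the
    constant common severity and run from weak-but-detectable at this
    cohort size up to complete within-set scrambling). Planted sets get
    genes reserved exclusively for them so null sets are genuinely
    untouched. ``noise_sd`` is in baseline-SD (log-expression) units;
    the default leaves the control cohort conserving roughly 85% of
    within-set orderings. ``paper_scale()`` gives the full-size stage
    layout (34/39/695/131 cases, 136 controls).
    """

    n_genes: int = 1000
    n_sets: int = 200
    set_size: tuple[int, int] = (10, 10)
    n_controls: int = 40
    n_cases: tuple[int, int, int, int] = (40, 40, 40, 40)
    noise_sd: float = 0.5
    n_common: int = 10
    n_progressive: int = 10
    pi_common: float = 0.5
    pi_progressive: tuple[float, float, float, float] = (0.4, 0.6, 0.8, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_size[0] < 2:
            raise ValueError("set_size must be >= 2")
        if self.n_common + self.n_progressive > self.n_sets:
            raise ValueError("more planted sets than sets")
        pis = self.pi_progressive
        if not all(0 <= p <= 1 for p in (*pis, self.pi_common)):
            raise ValueError("pi must lie in [0, 1]")
        if not all(a < b for a, b in zip(pis, pis[1:])):
            raise ValueError("progressive pi must strictly increase over stages")

    @classmethod
    def paper_scale(cls, **overrides) -> "SyntheticConfig":
        """Full-size stage layout (slower; for manual experiments)."""
        defaults = dict(n_controls=136, n_cases=(34, 39, 695, 131))
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SyntheticTruth:
    """Which sets were planted, and at what per-stage severity."""

    classes: dict[str, str]          # set_id -> null | common | progressive
    pi_by_stage: dict[str, dict[str, float]]  # set_id -> stage -> pi

    @property
    def common_ids(self) -> list[str]:
        return sorted(s for s, c in self.classes.items() if c == "common")

    @property
    def progressive_ids(self) -> list[str]:
        return sorted(s for s, c in self.classes.items() if c == "progressive")

    @property
    def planted_ids(self) -> list[str]:
        return sorted(s for s, c in self.classes.items() if c != "null")

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"classes": self.classes, "pi_by_stage": self.pi_by_stage},
            indent=2) + "\n", encoding="utf-8")

    @classmethod
    def read_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(classes=d["classes"], pi_by_stage=d["pi_by_stage"])


@dataclass
class SyntheticCohort:
    """Everything one simulated study comprises."""

    expression: ExpressionMatrix
    annotation: pd.DataFrame
    collection: GeneSetCollection
    truth: SyntheticTruth
    dag: GoDag = None
    mapping: TermMapping = None
    config: SyntheticConfig = None

    def case_ids(self, stage: str) -> list[str]:
        a = self.annotation
        return list(a.loc[a["group"] == stage, "sample_id"])

    @property
    def control_ids(self) -> list[str]:
        a = self.annotation
        return list(a.loc[a["group"] == "control", "sample_id"])


# ---------------------------------------------------------------------------
# Ontology + collection generation
# ---------------------------------------------------------------------------


def generate_ontology(n_terms: int, seed: int, *, n_genes: int = 1000,
                      set_size: tuple[int, int] = (10, 10),
                      immune_fraction: float = 0.4,
                      ) -> tuple[GoDag, GeneSetCollection, TermMapping]:
    """Random ontology DAG + one gene set per term + name-based mapping.

    The DAG has a single root, two designated immune ancestors at depth 1
    (reusing the real accessions GO:0002376 / GO:0006954 so downstream
    defaults apply) plus non-immune hubs; every later term attaches to
    1-2 parents drawn from the immune subtree with probability
    *immune_fraction*, else from the non-immune side, so the immune
    offspring cover roughly that fraction of terms. Deterministic in
    (n_terms, seed).
    """
    if n_terms < 4:
        raise ValueError("need n_terms >= 4")
    rng = np.random.default_rng(seed)
    graph = nx.MultiDiGraph()
    root = "GO:0008150"
    graph.add_node(root, name="biological process", namespace="biological_process")
    immune_roots = ["GO:0002376", "GO:0006954"]
    names = {"GO:0002376": "immune system process",
             "GO:0006954": "inflammatory response"}
    for t in immune_roots:
        graph.add_node(t, name=names[t], namespace="biological_process")
        graph.add_edge(t, root, key="is_a")
    n_hubs = max(1, min((n_terms - 3) // 10, n_terms - 3))
    hubs = []
    for h in range(n_hubs):
        tid = f"GO:{7000000 + h:07d}"
        graph.add_node(tid, name=f"cellular process {h}",
                       namespace="biological_process")
        graph.add_edge(tid, root, key="is_a")
        hubs.append(tid)
    immune_pool = list(immune_roots)
    other_pool = list(hubs)
    k = 0
    while graph.number_of_nodes() < n_terms:
        tid = f"GO:{1000000 + k:07d}"
        is_immune = rng.random() < immune_fraction
        pool = immune_pool if is_immune else other_pool
        n_par = 1 + (rng.random() < 0.3 and len(pool) > 1)
        parents = rng.choice(pool, size=min(n_par, len(pool)), replace=False)
        label = "immune function" if is_immune else "process"
        graph.add_node(tid, name=f"{label} {k}", namespace="biological_process")
        for j, p in enumerate(parents):
            rel = "part_of" if (j > 0 and rng.random() < 0.3) else "is_a"
            graph.add_edge(tid, p, key=rel)
        pool.append(tid)
        k += 1
    dag = GoDag(graph=graph)

    mapping: dict[str, str] = {}
    for tid in sorted(dag.term_ids):
        if tid == root:
            continue
        set_id = normalize_term_name(dag.name(tid)) + "_" + tid.replace(":", "_")
        mapping[set_id] = tid
    sets = _assign_members(list(mapping), rng, n_genes, set_size)
    collection = GeneSetCollection(sets=sets, source_tag=f"synthetic(seed={seed})")
    return dag, collection, TermMapping(mapping=mapping)


def _assign_members(set_ids: Sequence[str], rng: np.random.Generator,
                    n_genes: int, set_size: tuple[int, int],
                    exclusive: set[str] = frozenset(),
                    labels: dict[str, str] | None = None) -> list[GeneSet]:
    """Draw gene members for every set id.

    Sets in *exclusive* receive pairwise-disjoint genes reserved for them
    alone (no other set may contain them); the rest sample freely from
    the remaining universe, so only exclusive sets are insulated from
    perturbations planted in other sets.
    """
    genes = [f"G{i:05d}" for i in range(n_genes)]
    lo, hi = set_size
    sizes = {s: int(rng.integers(lo, hi + 1)) for s in set_ids}
    need = sum(sizes[s] for s in set_ids if s in exclusive)
    if need > n_genes:
        raise ValueError("gene universe too small for exclusive sets")
    pool = list(rng.permutation(genes))
    reserved, free = pool[:need], pool[need:]
    if not free:
        raise ValueError("no genes left for non-exclusive sets")
    sets = []
    cursor = 0
    for s in set_ids:
        if s in exclusive:
            members = reserved[cursor:cursor + sizes[s]]
            cursor += sizes[s]
        else:
            members = rng.choice(free, size=min(sizes[s], len(free)),
                                 replace=False)
        label = (labels or {}).get(s, s)
        sets.append(GeneSet(set_id=s, label=label, members=frozenset(members)))
    return sets


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _plant_disruption(values: np.ndarray, member_rows: np.ndarray, pi: float,
                      rng: np.random.Generator) -> None:
    """Permute a fraction *pi* of a set's member rows among themselves,
    independently per sample column, in place. Rounds to the nearest count
    but never below 2 genes when pi > 0."""
    if pi <= 0:
        return
    m = len(member_rows)
    n_disrupt = max(2, int(round(pi * m)))
    n_disrupt = min(n_disrupt, m)
    for col in range(values.shape[1]):
        chosen = rng.choice(member_rows, size=n_disrupt, replace=False)
        values[chosen, col] = values[rng.permutation(chosen), col]


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Simulate one staged cohort (expression + annotation + ontology +
    truth manifest), byte-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    dag, base_collection, mapping = generate_ontology(
        n_terms=config.n_sets + 1, seed=config.seed,
        n_genes=config.n_genes, set_size=config.set_size)
    set_ids = base_collection.set_ids
    if len(set_ids) < config.n_common + config.n_progressive:
        raise ValueError("collection smaller than requested planted sets")
    planted = rng.choice(set_ids, size=config.n_common + config.n_progressive,
                         replace=False)
    common_ids = set(planted[:config.n_common])
    progressive_ids = set(planted[config.n_common:])
    # planted sets get exclusive genes so null sets are genuinely untouched
    labels = {s.set_id: s.label for s in base_collection}
    collection = GeneSetCollection(
        _assign_members(set_ids, rng, config.n_genes, config.set_size,
                        exclusive=common_ids | progressive_ids, labels=labels),
        source_tag=f"synthetic(seed={config.seed})")

    classes = {}
    pi_by_stage: dict[str, dict[str, float]] = {}
    for s in set_ids:
        if s in common_ids:
            classes[s] = "common"
            pi_by_stage[s] = {st: config.pi_common for st in STAGES}
        elif s in progressive_ids:
            classes[s] = "progressive"
            pi_by_stage[s] = dict(zip(STAGES, config.pi_progressive))
        else:
            classes[s] = "null"
            pi_by_stage[s] = {st: 0.0 for st in STAGES}
    truth = SyntheticTruth(classes=classes, pi_by_stage=pi_by_stage)

    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    baseline = rng.normal(loc=7.0, scale=1.0, size=config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    def draw(n: int) -> np.ndarray:
        return (baseline[:, None]
                + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n)))

    blocks, sample_ids, ann_rows = [], [], []
    ctrl = draw(config.n_controls)
    for i in range(config.n_controls):
        sid = f"CTRL{i:04d}"
        sample_ids.append(sid)
        ann_rows.append({"sample_id": sid, "group": "control", "dataset_id": "D1"})
    blocks.append(ctrl)
    for stage, n_case in zip(STAGES, config.n_cases):
        vals = draw(n_case)
        for s in set_ids:
            pi = pi_by_stage[s][stage]
            if pi > 0:
                rows = np.array([gene_index[g] for g in sorted(collection[s].members)])
                _plant_disruption(vals, rows, pi, rng)
        blocks.append(vals)
        for i in range(n_case):
            sid = f"{stage.upper()}_{i:04d}"
            sample_ids.append(sid)
            ann_rows.append({"sample_id": sid, "group": stage, "dataset_id": "D1"})
    expr = ExpressionMatrix(genes, sample_ids, np.concatenate(blocks, axis=1))
    annot = pd.DataFrame(ann_rows).set_index("sample_id", drop=False)
    return SyntheticCohort(expression=expr, annotation=annot,
                           collection=collection, truth=truth,
                           dag=dag, mapping=mapping, config=config)


# ---------------------------------------------------------------------------
# Truth-based evaluation of pipeline outputs
# ---------------------------------------------------------------------------


def precision_recall(predicted: Sequence[str], relevant: Sequence[str],
                     ) -> dict[str, float | None]:
    pred, rel = set(predicted), set(relevant)
    tp = len(pred & rel)
    return {
        "precision": tp / len(pred) if pred else None,
        "recall": tp / len(rel) if rel else None,
        "n_predicted": len(pred),
        "n_relevant": len(rel),
    }


def end_to_end_truth_eval(rank_lists: dict[str, Sequence[str]],
                          progressive_out: Sequence[str],
                          common_out: Sequence[str],
                          truth: SyntheticTruth,
                          k: int = 20) -> dict:
    """Recovery metrics of pipeline outputs against the planted truth:
    top-*k* precision/recall vs planted sets per stage, progressive-filter
    precision/recall vs planted progressive sets, and common-intersection
    precision/recall vs all planted sets."""
    planted = set(truth.planted_ids)
    known = set(truth.classes)
    for name, ids in (("progressive", progressive_out), ("common", common_out)):
        bad = set(ids) - known
        if bad:
            raise ValueError(f"{name} output has unknown set ids: {sorted(bad)[:5]}")
    out: dict = {"top_k": {}, "k": k}
    for stage, ranked in rank_lists.items():
        bad = set(ranked) - known
        if bad:
            raise ValueError(f"{stage} ranking has unknown ids: {sorted(bad)[:5]}")
        out["top_k"][stage] = precision_recall(list(ranked)[:k], planted)
    out["progressive"] = precision_recall(progressive_out, truth.progressive_ids)
    out["common"] = precision_recall(common_out, planted)
    return out
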