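"""Shared fixtures: tiny hand-checkable objects plus one session-scoped
synthetic cohort (everything generated programmatically)."""

from __future__ import annotations

import numpy as np
import pytest

from gsrpipe.go_dag import GoDag
from gsrpipe.io_formats import ExpressionMatrix, GeneSet, GeneSetCollection
from gsrpipe.synthetic_data import SyntheticConfig, generate_cohort

import networkx as nx


@pytest.fixture
def abc_controls() -> ExpressionMatrix:
    """Three control samples over genes A,B,C whose majority ordering is
    A<B, A<C, B<C with supports 2/3, 3/3, 2/3."""
    return ExpressionMatrix(
        ["A", "B", "C"], ["s1", "s2", "s3"],
        np.array([[1.0, 1.0, 2.0],
                  [2.0, 3.0, 1.0],
                  [3.0, 2.0, 3.0]]))


@pytest.fixture
def abc_set() -> GeneSet:
    return GeneSet("SET_ABC", "abc", frozenset({"A", "B", "C"}))


@pytest.fixture
def abc_collection(abc_set) -> GeneSetCollection:
    return GeneSetCollection([abc_set])


def make_dag(edges, names=None, obsolete=()) -> GoDag:
    """Build a GoDag from (child, parent, relation) triples."""
    g = nx.MultiDiGraph()
    nodes = {n for c, p, _ in edges for n in (c, p)}
    nodes |= set(names or {})
    for n in sorted(nodes):
        g.add_node(n, name=(names or {}).get(n, n.replace("_", " ")),
                   namespace="biological_process")
    for c, p, rel in edges:
        g.add_edge(c, p, key=rel)
    return GoDag(graph=g, obsolete_ids=set(obsolete))


@pytest.fixture
def chain_dag() -> GoDag:
    """root <- a <- b via is_a."""
    return make_dag([("a", "root", "is_a"), ("b", "a", "is_a")])


@pytest.fixture
def diamond_dag() -> GoDag:
    """d is_a b, d is_a c, b and c is_a root."""
    return make_dag([("b", "root", "is_a"), ("c", "root", "is_a"),
                     ("d", "b", "is_a"), ("d", "c", "is_a")])


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic preset (200 sets, 20 planted, 40/arm), seed 0."""
    return generate_cohort(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort for pipeline-level tests."""
    return generate_cohort(SyntheticConfig(
        seed=3, n_genes=300, n_sets=40, n_controls=16,
        n_cases=(12, 12, 12, 12), n_common=4, n_progressive=4))
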