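"""Shared fixtures: taxonomy builders, random trees, independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from lecatrace.simulate import GroupSpec, SimulationConfig
from lecatrace.taxonomy import TaxonomyMap, TaxonRecord
from lecatrace.trees import GeneTree, parse_newick


def build_taxonomy(spec: dict) -> TaxonomyMap:
    """spec: label -> (species, group, domain, supergroup)."""
    return TaxonomyMap(
        TaxonRecord(label, *fields) for label, fields in spec.items())


@pytest.fixture
def make_taxonomy():
    return build_taxonomy


def random_tree(rng: np.random.Generator, labels: list[str],
                multifurcating: bool = False) -> GeneTree:
    """Random topology over the labels with exponential branch lengths."""
    pool = [f"{lab}:{rng.exponential(0.5) + 0.01:.4f}" for lab in labels]
    while len(pool) > 1:
        arity = 2
        if multifurcating and len(pool) > 3 and rng.random() < 0.3:
            arity = 3
        picks = sorted(rng.choice(len(pool), size=arity, replace=False),
                       reverse=True)
        parts = [pool.pop(i) for i in picks]
        pool.append(f"({','.join(parts)}):{rng.exponential(0.5) + 0.01:.4f}")
    return parse_newick(pool[0] + ";")


@pytest.fixture
def make_random_tree():
    return random_tree


# --------------------------------------------------------- brute-force oracles

def oracle_bipartition_sides(tree: GeneTree) -> set[frozenset]:
    """All bipartition sides by explicit edge removal on a networkx graph."""
    import networkx as nx

    graph = nx.Graph()
    for u, v in tree.edges():
        graph.add_edge(u, v)
    sides: set[frozenset] = set()
    for u, v in tree.edges():
        graph.remove_edge(u, v)
        for component in nx.connected_components(graph):
            side = frozenset(tree.label_of(n) for n in component
                             if tree.label_of(n) is not None)
            if side:
                sides.add(side)
        graph.add_edge(u, v)
    return sides


def oracle_is_clan(tree: GeneTree, leafset: frozenset) -> bool:
    if leafset == tree.leaves or len(leafset) == 1:
        return True
    return leafset in oracle_bipartition_sides(tree)


def oracle_sister(tree: GeneTree, clan: frozenset):
    """Sister group by explicit graph surgery; None when base multifurcates."""
    import networkx as nx

    graph = nx.Graph()
    for u, v in tree.edges():
        graph.add_edge(u, v)

    def leafset(nodes):
        return frozenset(tree.label_of(n) for n in nodes
                         if tree.label_of(n) is not None)

    for u, v in tree.edges():
        graph.remove_edge(u, v)
        comps = list(nx.connected_components(graph))
        graph.add_edge(u, v)
        for comp in comps:
            if leafset(comp) == clan:
                base = u if v in comp else v
                if tree.label_of(base) is not None:
                    return frozenset((tree.label_of(base),))
                graph.remove_node(base)
                pieces = [leafset(c) for c in nx.connected_components(graph)
                          if leafset(c) != clan]
                graph.add_node(base)
                for a, b in tree.edges():
                    if base in (a, b):
                        graph.add_edge(a, b)
                if len(pieces) != 2:
                    return None
                a, b = pieces
                if len(a) != len(b):
                    return min(a, b, key=len)
                return min(a, b, key=lambda s: tuple(sorted(s)))
    raise AssertionError("not a clan")


# ------------------------------------------------------------- small designs

SMALL_DESIGN = (
    GroupSpec("Alphaproteobacteria", "Bacteria", 10),
    GroupSpec("Cyanobacteria", "Bacteria", 8),
    GroupSpec("Deltaproteobacteria", "Bacteria", 8),
    GroupSpec("Euryarchaeota", "Archaea", 10),
    GroupSpec("Crenarchaeota", "Archaea", 6),
)


@pytest.fixture
def small_cfg():
    def factory(**overrides) -> SimulationConfig:
        defaults = dict(seed=0, prokaryote_groups=SMALL_DESIGN,
                        scenario="EGT_FROM",
                        donor_group="Alphaproteobacteria", n_replicates=20)
        defaults.update(overrides)
        return SimulationConfig(**defaults)
    return factory
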