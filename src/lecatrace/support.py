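"""Support statistics for the branching position of a LECA clade.

Classical branch bootstrap support cannot characterize where a clade attaches
among prokaryotes, because the attachment is a node, not a single branch. Two
measures are used instead:

* **NBS** (node bootstrap support): the percentage of bootstrap replicate
  trees containing the tripartition at the node at the base of the clade's
  stem — equivalently, in which the three bipartitions adjacent to that node
  co-occur.
* **SGS** (sister-group stability): the mean pairwise similarity of the
  clade's sister-group leaf sets across bootstrap replicates,

  .. math:: SGS = \\frac{2}{N(N-1)} \\sum_{i<j} s(G_i, G_j)

  where ``G_i`` is the sister group (the smaller of the two prokaryotic
  subtrees at the base of the clade) in replicate *i* and ``s`` is the Jaccard
  index ``|G_i ∩ G_j| / |G_i ∪ G_j|``; ``s = 0`` whenever the clade is
  paraphyletic (or its base unresolved) in either replicate. SGS ranges from 0
  (complete disjunction between sister groups) to 1 (absolute stability) and
  is the more relaxed of the two: replicates may disagree on the exact
  attachment node while still placing the clade next to the same organisms.

The module also provides taxon monophyly support across replicates, the
near-universal cluster filter, and the calibration of an SGS decision
threshold against a reference set of clades with known expected origin.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .taxonomy import TaxonomyMap
from .trees import DegenerateBaseError, GeneTree, NotAClanError


class SupportError(ValueError):
    pass


def jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


@dataclass(frozen=True)
class CladeSupportReport:
    clade_id: str
    g_ml: frozenset            # sister group in the ML tree
    nbs: float                 # percent, 0-100
    sgs: float                 # fraction, 0-1
    n_replicates: int
    replicate_sisters: tuple   # per-replicate sister sets (None = paraphyletic)

    @property
    def sgs_percent(self) -> float:
        return 100.0 * self.sgs


def _check_leafsets(trees: Sequence[GeneTree], reference: frozenset) -> None:
    for i, t in enumerate(trees):
        if t.leaves != reference:
            raise SupportError(
                f"replicate {i + 1} has a different leaf set than the ML tree")


def nbs(ml_tree: GeneTree, bootstrap_trees: Sequence[GeneTree],
        clade_leaves: Iterable[str]) -> float:
    """Percentage of replicates containing the ML tree's base tripartition.

    Replicates in which the clade is not a clan (or any of the three
    bipartitions is absent) contribute zero.
    """
    clade = frozenset(clade_leaves)
    if not bootstrap_trees:
        raise SupportError("need at least one bootstrap tree")
    _check_leafsets(bootstrap_trees, ml_tree.leaves)
    tri = ml_tree.tripartition_at_base(clade)  # raises if not a clan
    hits = sum(1 for rep in bootstrap_trees if rep.contains_tripartition(tri))
    return 100.0 * hits / len(bootstrap_trees)


def replicate_sister_sets(bootstrap_trees: Sequence[GeneTree],
                          clade_leaves: Iterable[str]
                          ) -> list[frozenset | None]:
    """Sister group of the clade in every replicate; None where the clade is
    paraphyletic or its base is multifurcating."""
    clade = frozenset(clade_leaves)
    out: list[frozenset | None] = []
    for rep in bootstrap_trees:
        try:
            result = rep.sister_group(clade)
        except NotAClanError:
            out.append(None)
            continue
        out.append(result.leaves if result.resolved else None)
    return out


def sgs(bootstrap_trees: Sequence[GeneTree], clade_leaves: Iterable[str],
        similarity: Callable[[frozenset, frozenset], float] = jaccard
        ) -> float:
    """Mean pairwise sister-group similarity over all replicate pairs."""
    n = len(bootstrap_trees)
    if n < 2:
        raise SupportError("SGS needs at least 2 bootstrap trees")
    _check_leafsets(bootstrap_trees[1:], bootstrap_trees[0].leaves)
    sisters = replicate_sister_sets(bootstrap_trees, clade_leaves)
    return sgs_from_sister_sets(sisters, similarity)


def sgs_from_sister_sets(sisters: Sequence[frozenset | None],
                         similarity: Callable[[frozenset, frozenset], float]
                         = jaccard) -> float:
    n = len(sisters)
    if n < 2:
        raise SupportError("SGS needs at least 2 replicates")
    # collapse identical sister sets: the pair sum only depends on multiplicities
    counts = Counter(s for s in sisters if s is not None)
    unique = list(counts)
    total = 0.0
    for i, a in enumerate(unique):
        ca = counts[a]
        total += similarity(a, a) * ca * (ca - 1) / 2.0
        for b in unique[i + 1:]:
            total += similarity(a, b) * ca * counts[b]
    return 2.0 * total / (n * (n - 1))


def clade_support(clade_id: str, ml_tree: GeneTree,
                  bootstrap_trees: Sequence[GeneTree],
                  clade_leaves: Iterable[str]) -> CladeSupportReport:
    """NBS, SGS and the ML sister group for one clade, in one pass."""
    clade = frozenset(clade_leaves)
    _check_leafsets(bootstrap_trees, ml_tree.leaves)
    g_ml = ml_tree.sister_group(clade).leaves
    sisters = replicate_sister_sets(bootstrap_trees, clade)
    try:
        nbs_value = nbs(ml_tree, bootstrap_trees, clade)
    except DegenerateBaseError:
        nbs_value = float("nan")
    return CladeSupportReport(
        clade_id=clade_id,
        g_ml=g_ml,
        nbs=nbs_value,
        sgs=sgs_from_sister_sets(sisters),
        n_replicates=len(bootstrap_trees),
        replicate_sisters=tuple(sisters),
    )


def monophyly_support(bootstrap_trees: Sequence[GeneTree],
                      taxon_leaves: Iterable[str]) -> float:
    """Percentage of replicates in which the taxon's leaves form a clan."""
    taxon = frozenset(taxon_leaves)
    if not taxon:
        raise SupportError("empty taxon set")
    if not bootstrap_trees:
        raise SupportError("need at least one bootstrap tree")
    hits = sum(1 for rep in bootstrap_trees if rep.is_clan(taxon))
    return 100.0 * hits / len(bootstrap_trees)


def near_universal_filter(cluster_species: Mapping[str, Iterable[str]],
                          tax: TaxonomyMap, fraction: float = 0.9) -> bool:
    """Does a gene family qualify as (nearly) universal?

    True iff, for each prokaryotic domain, the family has representatives for
    at least ``fraction`` of the species sampled in that domain (count
    rounded up). Only such widely distributed, vertically inherited genes are
    informative about domain-level relationships.
    """
    if not 0.0 < fraction <= 1.0:
        raise SupportError("fraction must be in (0, 1]")
    totals = tax.domain_species_totals()
    for domain in ("Archaea", "Bacteria"):
        total = totals.get(domain, 0)
        if total == 0:
            return False
        present = len(set(cluster_species.get(domain, ())))
        if present < math.ceil(fraction * total):
            return False
    return True


@dataclass(frozen=True)
class CalibrationResult:
    """SGS threshold calibrated on clades of known expected origin.

    ``threshold`` is the smallest SGS value t (percent) such that every
    reference clade with SGS strictly above t is assigned to the expected
    group; ``usable`` is False when no reference lies above the threshold.
    """

    table: tuple                # (clade_id, sgs_percent, group, correct) desc.
    threshold: float            # percent
    expected_group: str
    usable: bool


def calibrate_sgs_threshold(reference: Sequence[tuple[str, float, str]],
                            expected_group: str) -> CalibrationResult:
    """Calibrate the SGS decision threshold on a reference clade set.

    ``reference`` holds (clade_id, SGS percent, assigned group) triples, e.g.
    clades of genes whose organellar origin is known in advance. The threshold
    is the largest SGS among incorrectly assigned clades (0 when all are
    correct); everything above it is correctly assigned by construction.
    """
    if not reference:
        raise SupportError("need at least one reference clade")
    rows = sorted(((cid, float(s), grp, grp == expected_group)
                   for cid, s, grp in reference),
                  key=lambda r: (-r[1], r[0]))
    wrong = [s for _, s, _, ok in rows if not ok]
    threshold = max(wrong) if wrong else 0.0
    usable = any(s > threshold for _, s, _, ok in rows if ok)
    return CalibrationResult(table=tuple(rows), threshold=threshold,
                             expected_group=expected_group, usable=usable)
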