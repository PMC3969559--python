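"""Detection of LECA clades in gene-family trees.

A LECA clade is a maximal clan of exclusively eukaryotic sequences that can be
traced back to the last eukaryotic common ancestor. Ancestrality is decided by
species (not sequence) counts across eukaryotic supergroups, under three
alternative rules:

* R1 — at least two Unikont species and two Plantae species;
* R2 — at least two Unikont species and two Chromalveolate species;
* R3 — at least two Plantae, two Chromalveolate and one Kinetoplastid species.

An opisthokont-only clade never qualifies: every rule demands two supergroups,
which guards against mistaking lineage-specific genes for ancestral ones.

Prokaryotic "intruders" — small prokaryotic clans nested among diverse
eukaryotes, typically recent eukaryote-to-prokaryote transfers — would split a
genuine LECA clade in two. :func:`flag_intruders` replaces the manual tree
inspection such cases otherwise require with an explicit, logged heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .taxonomy import TaxonomyMap
from .trees import GeneTree

logger = logging.getLogger(__name__)

RULES = ("R1", "R2", "R3")


@dataclass(frozen=True)
class LecaClade:
    cluster_id: str
    leaves: frozenset
    rules_satisfied: frozenset
    representatives: frozenset = frozenset()
    intruders_removed: tuple = ()

    @property
    def is_leca(self) -> bool:
        return bool(self.rules_satisfied)


def _maximal_pure_clans(tree: GeneTree, tax: TaxonomyMap,
                        eukaryotic: bool) -> list[frozenset]:
    """Maximal clans whose leaves are all eukaryotic (or all prokaryotic)."""
    target = {x for x in tree.leaves
              if tax.is_eukaryote(x) == eukaryotic}
    if not target:
        return []
    other = tree.leaves - target
    if not other:
        return [frozenset(target)]
    # orient the tree at a leaf of the other kind: maximal pure clans are then
    # exactly the maximal pure subtrees
    root = tree.node_of_label(min(other))
    parent: dict[int, int | None] = {root: None}
    order = [root]
    stack = [root]
    while stack:
        v = stack.pop()
        for w in tree.neighbors(v):
            if w != parent[v]:
                parent[w] = v
                order.append(w)
                stack.append(w)
    pure: dict[int, bool] = {}
    members: dict[int, frozenset] = {}
    for v in reversed(order):
        kids = [w for w in tree.neighbors(v) if w != parent[v]]
        lab = tree.label_of(v)
        if lab is not None:
            pure[v] = lab in target
            members[v] = frozenset((lab,))
        else:
            pure[v] = all(pure[w] for w in kids)
            members[v] = frozenset().union(*(members[w] for w in kids))
    out = []
    stack = [root]
    while stack:
        v = stack.pop()
        if pure[v] and v != root:
            out.append(members[v])
            continue
        stack.extend(w for w in tree.neighbors(v) if w != parent[v])
    return sorted(out, key=lambda s: tuple(sorted(s)))


def extract_euk_clades(tree: GeneTree, tax: TaxonomyMap) -> list[frozenset]:
    """All maximal clans of exclusively eukaryotic leaves.

    The returned clans are pairwise disjoint and their union is the set of all
    eukaryotic leaves; a tree with no eukaryotes yields an empty list.
    """
    return _maximal_pure_clans(tree, tax, eukaryotic=True)


def flag_intruders(tree: GeneTree, tax: TaxonomyMap,
                   max_intruder_size: int = 2,
                   min_supergroups: int = 2) -> list[str]:
    """Prokaryotic leaves whose removal would merge separated eukaryote clans.

    A maximal prokaryotic clan of at most ``max_intruder_size`` leaves is
    flagged when pruning it merges two or more eukaryotic clans that jointly
    span at least ``min_supergroups`` eukaryotic supergroups. Flagged leaves
    are only reported; pruning is the caller's decision.
    """
    if max_intruder_size < 1:
        raise ValueError("max_intruder_size must be >= 1")
    base = extract_euk_clades(tree, tax)
    if len(base) < 2:
        return []
    flagged: set[str] = set()
    for prok_clan in _maximal_pure_clans(tree, tax, eukaryotic=False):
        if len(prok_clan) > max_intruder_size:
            continue
        remaining = tree.leaves - prok_clan
        if len(remaining) < 2:
            continue
        pruned = tree.restrict_to(remaining)
        for clan in extract_euk_clades(pruned, tax):
            merged = [b for b in base if b <= clan]
            if len(merged) < 2:
                continue
            union = frozenset().union(*merged)
            supergroups = {tax.supergroup(x) for x in union}
            if len(supergroups) >= min_supergroups:
                flagged |= prok_clan
                logger.info("intruder clan %s merges %d eukaryote clans "
                            "spanning supergroups %s",
                            sorted(prok_clan), len(merged), sorted(supergroups))
                break
    return sorted(flagged)


def passes_leca_criteria(leaves, tax: TaxonomyMap) -> frozenset:
    """Which ancestrality rules a eukaryotic leaf set satisfies.

    Counts distinct species per supergroup (paralogs never inflate counts).
    Returns the subset of {R1, R2, R3} satisfied; empty means the clade cannot
    be traced back to LECA.
    """
    leaves = frozenset(leaves)
    if not leaves:
        raise ValueError("empty leaf set")
    species: dict[str, set[str]] = {}
    for x in leaves:
        rec = tax[x]
        if not rec.is_eukaryote:
            raise ValueError(f"non-eukaryotic leaf {x!r} in a LECA candidate")
        species.setdefault(rec.supergroup, set()).add(rec.species_id)
    count = {sg: len(sp) for sg, sp in species.items()}
    uni = count.get("Unikonts", 0)
    pla = count.get("Plantae", 0)
    chr_ = count.get("Chromalveolates", 0)
    kin = count.get("Kinetoplastids", 0)
    rules = set()
    if uni >= 2 and pla >= 2:
        rules.add("R1")
    if uni >= 2 and chr_ >= 2:
        rules.add("R2")
    if pla >= 2 and chr_ >= 2 and kin >= 1:
        rules.add("R3")
    return frozenset(rules)


def detect_leca_clades(tree: GeneTree, tax: TaxonomyMap, cluster_id: str,
                       max_intruder_size: int = 2,
                       auto_prune: bool = True) -> tuple[list[LecaClade], GeneTree]:
    """Full detection for one family: flag/prune intruders, extract clans,
    evaluate the ancestrality rules.

    Returns every eukaryotic clan as a :class:`LecaClade` (non-LECA clans have
    an empty rule set) together with the tree actually used (pruned of
    intruders when ``auto_prune``).
    """
    missing = tax.missing(tree.leaves)
    if missing:
        raise ValueError(f"leaves absent from taxonomy: {missing[:5]}")
    intruders: tuple = ()
    work = tree
    if max_intruder_size >= 1:
        flagged = flag_intruders(tree, tax, max_intruder_size)
        if flagged and auto_prune:
            remaining = tree.leaves - set(flagged)
            proks_left = any(tax[x].is_prokaryote for x in remaining)
            if len(remaining) >= 2 and proks_left:
                work = tree.restrict_to(remaining)
                intruders = tuple(flagged)
                logger.info("%s: pruned %d intruder leaves", cluster_id,
                            len(flagged))
            else:
                logger.warning("%s: flagged clans %s not pruned (would leave "
                               "no prokaryotes)", cluster_id, flagged)
    clades = []
    for i, clan in enumerate(extract_euk_clades(work, tax), start=1):
        rules = passes_leca_criteria(clan, tax) if len(clan) >= 1 else frozenset()
        clades.append(LecaClade(
            cluster_id=cluster_id,
            leaves=clan,
            rules_satisfied=rules,
            intruders_removed=intruders,
        ))
    return clades, work
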