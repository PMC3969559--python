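"""Taxonomy-aware configuration classification of LECA clades.

A configuration is the topological label describing where a LECA clade
branches among its prokaryotic homologs, with explicit requirements on how
many species of the candidate taxon are represented:

* ``GROUP_RELATED`` — the clade branches inside a clan whose prokaryotic
  members all belong to one group (phylum, or class for Proteobacteria and
  Firmicutes) representing at least the group's threshold of distinct species;
* ``BACTERIAL_DOMAIN_RELATED`` / ``ARCHAEAL_DOMAIN_RELATED`` — same at the
  domain level, requiring at least ``domain_min`` (default 10) species, when
  no group qualifies;
* ``THREE_DOMAIN`` — Eukarya, Bacteria and Archaea are each monophyletic and
  both prokaryotic domains are represented by at least ``three_domain_min``
  species;
* ``UNCLEAR`` — none of the above (typically archaeal and bacterial sequences
  interleave around the eukaryote attachment);
* ``PARAPHYLETIC`` — the clade's sequences do not even form a clan.

The species thresholds make the classification robust to single transferred
sequences: an isolated foreign leaf as the sister group (a recent HGT) cannot
pull the label to its group, unlike the naive sister-clade-identity criterion
(:func:`classify_naive`) provided for comparison.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .taxonomy import TaxonomyMap
from .trees import GeneTree

logger = logging.getLogger(__name__)

GROUP_RELATED = "GROUP_RELATED"
BACTERIAL_DOMAIN_RELATED = "BACTERIAL_DOMAIN_RELATED"
ARCHAEAL_DOMAIN_RELATED = "ARCHAEAL_DOMAIN_RELATED"
THREE_DOMAIN = "THREE_DOMAIN"
UNCLEAR = "UNCLEAR"
PARAPHYLETIC = "PARAPHYLETIC"

KINDS = (GROUP_RELATED, BACTERIAL_DOMAIN_RELATED, ARCHAEAL_DOMAIN_RELATED,
         THREE_DOMAIN, UNCLEAR, PARAPHYLETIC)

HALF = "HALF"
NEVER = "NEVER"

# Reference prokaryotic sampling: distinct species per group and the minimal
# number of species a configuration must represent (HALF = half the sampled
# species, rounded up; NEVER = too poorly sampled to ever be assigned).
DEFAULT_GROUP_TABLE: dict[str, tuple[int, int | str]] = {
    "Acidobacteria": (3, 3),
    "Actinobacteria": (15, HALF),
    "Alphaproteobacteria": (10, HALF),
    "Aquificae": (4, 3),
    "Bacilli": (9, HALF),
    "Bacteroidetes": (15, HALF),
    "Betaproteobacteria": (4, 3),
    "Chlamydiae": (3, 3),
    "Chlorobi": (5, 4),
    "Chloroflexi": (5, 4),
    "Clostridia": (9, HALF),
    "Crenarchaeota": (11, HALF),
    "Cyanobacteria": (15, HALF),
    "Deinococcus-Thermus": (2, NEVER),
    "Deltaproteobacteria": (8, HALF),
    "Dictyoglomi": (1, NEVER),
    "Elusimicrobia": (2, NEVER),
    "Epsilonproteobacteria": (5, 3),
    "Euryarchaeota": (25, HALF),
    "Fusobacteria": (1, NEVER),
    "Gammaproteobacteria": (7, HALF),
    "Gemmatimonadetes": (1, NEVER),
    "Korarchaeota": (1, NEVER),
    "Mollicutes": (4, 3),
    "Nitrospirae": (1, NEVER),
    "Planctomycetes": (3, 3),
    "Spirochaetes": (4, 3),
    "Thaumarchaeota": (2, NEVER),
    "Thermotogae": (4, 3),
    "unclassified Proteobacteria": (1, NEVER),
    "Verrucomicrobia": (3, 3),
}

class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class GroupThresholds:
    """Minimal species representation required per group and per domain."""

    groups: Mapping[str, tuple[int, int | str]]
    domain_min: int = 10
    three_domain_min: Mapping[str, int] = None

    def __post_init__(self):
        if self.three_domain_min is None:
            object.__setattr__(self, "three_domain_min",
                               {"Archaea": 10, "Bacteria": 10})
        for group, (sampled, rule) in self.groups.items():
            if isinstance(rule, str) and rule not in (HALF, NEVER):
                raise ConfigurationError(
                    f"{group}: threshold must be an int, {HALF} or {NEVER}")

    @staticmethod
    def default() -> "GroupThresholds":
        return GroupThresholds(groups=dict(DEFAULT_GROUP_TABLE))

    def resolved(self, group: str) -> int | None:
        """Species threshold for a group; None if it can never be assigned."""
        if group not in self.groups:
            raise ConfigurationError(f"group {group!r} has no threshold entry")
        sampled, rule = self.groups[group]
        if rule == NEVER:
            return None
        if rule == HALF:
            return math.ceil(sampled / 2)
        return int(rule)

    def with_overrides(self, overrides: Mapping[str, tuple[int, int | str]]
                       ) -> "GroupThresholds":
        merged = dict(self.groups)
        merged.update(overrides)
        return GroupThresholds(merged, self.domain_min,
                               dict(self.three_domain_min))

    @staticmethod
    def from_yaml(path) -> "GroupThresholds":
        with open(path, encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        groups = {name: (int(entry["sampled"]), entry["threshold"])
                  for name, entry in (data.get("groups") or {}).items()}
        base = dict(DEFAULT_GROUP_TABLE)
        base.update(groups)
        return GroupThresholds(
            groups=base,
            domain_min=int(data.get("domain_min", 10)),
            three_domain_min=dict(data.get("three_domain_min",
                                           {"Archaea": 10, "Bacteria": 10})),
        )


@dataclass(frozen=True)
class ConfigurationLabel:
    kind: str
    group: str | None = None
    evidence: tuple | None = None  # (enclosing clan leaf set, species count)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown configuration kind {self.kind!r}")
        if (self.group is not None) != (self.kind == GROUP_RELATED):
            raise ConfigurationError("group is set iff kind is GROUP_RELATED")

    @property
    def key(self) -> tuple:
        return (self.kind, self.group)

    def __str__(self) -> str:
        return f"{self.kind}({self.group})" if self.group else self.kind


# sort key for modal tie-breaking: most specific configuration first
_PRECEDENCE = {GROUP_RELATED: 0, THREE_DOMAIN: 1, ARCHAEAL_DOMAIN_RELATED: 2,
               BACTERIAL_DOMAIN_RELATED: 2, UNCLEAR: 3, PARAPHYLETIC: 4}


def _label_sort_key(key: tuple) -> tuple:
    kind, group = key
    return (_PRECEDENCE[kind], group or "", kind)


def classify_configuration(tree: GeneTree, clade_leaves: Iterable[str],
                           tax: TaxonomyMap,
                           thr: GroupThresholds | None = None
                           ) -> ConfigurationLabel:
    """Configuration of one LECA clade in one tree.

    ``clade_leaves`` are the clade's (representative) sequences. The clan
    enclosing them that qualifies a taxon is the *largest* clan containing the
    clade whose prokaryotic members all belong to that taxon (qualifying clans
    for a fixed taxon are nested, so the largest carries the most species);
    eukaryotic leaves inside the clan are ignored for species counts.

    "Branching inside" a taxon's clan additionally requires the clade to be
    embedded in it, not merely adjacent: at the node at the base of the
    clade's stem, at least two of the other subtrees must contain members of
    the enclosing clan. Without this, in a perfect three-domain topology the
    complement of the archaeal clan is a pure-bacterial clan containing the
    eukaryotes (and vice versa), and the three-domain configuration could
    never be reached.
    """
    thr = thr or GroupThresholds.default()
    clade = frozenset(clade_leaves)
    if not clade:
        raise ConfigurationError("empty clade")
    if not clade <= tree.leaves:
        raise ConfigurationError("clade leaves missing from tree")
    info = {x: tax[x] for x in tree.leaves}  # raises naming any unknown leaf
    prok_leaves = [x for x, r in info.items() if r.is_prokaryote]
    if not prok_leaves:
        raise ConfigurationError("tree contains no prokaryotic leaves")
    stem = tree.clan_edge(clade)
    if stem is None:
        if clade == tree.leaves:
            raise ConfigurationError("clade covers the whole tree")
        return ConfigurationLabel(PARAPHYLETIC)

    # subtrees around the node at the base of the clade's stem
    base, into_clan = stem
    if tree.is_leaf(base):
        base_parts = [frozenset((tree.label_of(base),))]
    else:
        base_parts = [tree.subtree_leaves(base, w)
                      for w in tree.neighbors(base) if w != into_clan]

    def embedded(clan: frozenset) -> bool:
        return sum(1 for part in base_parts
                   if not part.isdisjoint(clan)) >= 2

    groups = sorted({info[x].group for x in prok_leaves})
    gid = {g: i for i, g in enumerate(groups)}
    group_domain = {info[x].group: info[x].domain for x in prok_leaves}

    nodes = list(tree.postorder())
    idx = {v: i for i, v in enumerate(nodes)}
    n_nodes = len(nodes)
    K = len(groups)
    M = np.zeros((n_nodes, K), dtype=np.int32)      # prok sequences per group
    prok = np.zeros(n_nodes, dtype=np.int32)
    in_clade = np.zeros(n_nodes, dtype=np.int32)
    has_parent = np.zeros(n_nodes, dtype=bool)
    for i, v in enumerate(nodes):
        lab = tree.label_of(v)
        if lab is not None:
            rec = info[lab]
            if rec.is_prokaryote:
                M[i, gid[rec.group]] = 1
                prok[i] = 1
            if lab in clade:
                in_clade[i] = 1
        for w in tree.children_of(v):
            j = idx[w]
            M[i] += M[j]
            prok[i] += prok[j]
            in_clade[i] += in_clade[j]
        has_parent[i] = tree.parent_of(v) is not None

    k_clade = len(clade)
    root_i = next(i for i in range(n_nodes) if not has_parent[i])
    G_tot = M[root_i].copy()
    P_tot = int(G_tot.sum())

    def leafset_of(i: int, complement: bool) -> frozenset:
        v = nodes[i]
        p = tree.parent_of(v)
        side = tree.subtree_leaves(p, v)
        return tree.leaves - side if complement else side

    def best_enclosing(counts_col: np.ndarray, col_total: int
                       ) -> tuple[frozenset, int] | None:
        """Largest clan containing the clade whose prok members all belong to
        the taxon with per-node subtree counts ``counts_col``; returns the
        clan and its sequence count, or None."""
        if col_total == P_tot:
            return tree.leaves, col_total
        best: tuple[int, int, bool] | None = None  # (count, node index, comp?)
        sub = has_parent & (in_clade == k_clade) & (prok == counts_col) \
            & (counts_col > 0)
        for i in np.nonzero(sub)[0]:
            c = int(counts_col[i])
            if best is None or c > best[0]:
                best = (c, int(i), False)
        comp_count = col_total - counts_col
        comp = has_parent & (in_clade == 0) \
            & ((P_tot - prok) == comp_count) & (comp_count > 0)
        for i in np.nonzero(comp)[0]:
            c = int(comp_count[i])
            if best is None or c > best[0]:
                best = (c, int(i), True)
        if best is None:
            return None
        return leafset_of(best[1], best[2]), best[0]

    def species_count(clan: frozenset, member: set[str] | None = None) -> int:
        labels = (x for x in clan if info[x].is_prokaryote
                  and (member is None or x in member))
        return len({info[x].species_id for x in labels})

    # --- group level -------------------------------------------------------
    eligible_groups: list[tuple[int, str, frozenset, int]] = []
    for g in groups:
        threshold = thr.resolved(g)
        if threshold is None:
            continue
        found = best_enclosing(M[:, gid[g]], int(G_tot[gid[g]]))
        if found is None:
            continue
        clan, _ = found
        if not embedded(clan):
            continue
        n_species = species_count(clan)
        if n_species >= threshold:
            eligible_groups.append((len(clan), g, clan, n_species))
    if eligible_groups:
        if len(eligible_groups) > 1:
            logger.info("multiple eligible groups %s; keeping the most "
                        "specific", [g for _, g, _, _ in eligible_groups])
        eligible_groups.sort(key=lambda t: (t[0], t[1]))
        _, g, clan, n_species = eligible_groups[0]
        return ConfigurationLabel(GROUP_RELATED, group=g,
                                  evidence=(clan, n_species))

    # --- domain level ------------------------------------------------------
    domain_cols: dict[str, np.ndarray] = {}
    for domain in ("Archaea", "Bacteria"):
        cols = [gid[g] for g in groups if group_domain[g] == domain]
        if cols:
            domain_cols[domain] = M[:, cols].sum(axis=1)
    eligible_domains: list[tuple[str, frozenset, int]] = []
    for domain, col in domain_cols.items():
        found = best_enclosing(col, int(G_tot[[gid[g] for g in groups
                                               if group_domain[g] == domain]].sum()))
        if found is None:
            continue
        clan, _ = found
        if not embedded(clan):
            continue
        n_species = len({info[x].species_id for x in clan
                         if info[x].domain == domain})
        if n_species >= thr.domain_min:
            eligible_domains.append((domain, clan, n_species))
    if len(eligible_domains) == 1:
        domain, clan, n_species = eligible_domains[0]
        kind = (ARCHAEAL_DOMAIN_RELATED if domain == "Archaea"
                else BACTERIAL_DOMAIN_RELATED)
        return ConfigurationLabel(kind, evidence=(clan, n_species))
    # Both domains qualifying is the signature of the three-domain topology
    # (each domain clan's complement is the eukaryotes plus the other domain),
    # not of a genuine domain relationship: fall through to the test below.

    # --- three-domain ------------------------------------------------------
    by_domain: dict[str, set[str]] = {}
    for x, rec in info.items():
        by_domain.setdefault(rec.domain, set()).add(x)
    if all(d in by_domain for d in ("Eukarya", "Archaea", "Bacteria")):
        monophyletic = all(tree.is_clan(by_domain[d])
                           for d in ("Eukarya", "Archaea", "Bacteria"))
        rich_enough = all(
            len({info[x].species_id for x in by_domain[d]})
            >= thr.three_domain_min[d]
            for d in ("Archaea", "Bacteria"))
        if monophyletic and rich_enough:
            return ConfigurationLabel(THREE_DOMAIN)
    return ConfigurationLabel(UNCLEAR)


def classify_naive(tree: GeneTree, clade_leaves: Iterable[str],
                   tax: TaxonomyMap) -> str:
    """Sister-clade-identity criterion: the lowest-rank taxon shared by every
    member of the clade's sister group (group, else domain, else "mixed").

    Over-confident by construction — a single transferred sequence as sister
    names its own group — and provided for contrast with
    :func:`classify_configuration`.
    """
    clade = frozenset(clade_leaves)
    if not tree.is_clan(clade):
        raise ConfigurationError("clade is paraphyletic; naive criterion undefined")
    sister = tree.sister_group(clade).leaves
    groups = {tax.group(x) for x in sister}
    if len(groups) == 1:
        return next(iter(groups))
    domains = {tax.domain(x) for x in sister}
    if len(domains) == 1:
        return next(iter(domains))
    return "mixed"


@dataclass(frozen=True)
class ConfigurationProfile:
    """Per-label frequencies of a clade's configuration across bootstrap
    replicates, the modal label, and per-group association fractions."""

    frequencies: Mapping[tuple, float]   # label key -> fraction of replicates
    modal: ConfigurationLabel
    group_fractions: Mapping[str, float]
    n_replicates: int

    def frequency(self, kind: str, group: str | None = None) -> float:
        return self.frequencies.get((kind, group), 0.0)


def bootstrap_configuration_profile(bootstrap_trees: Sequence[GeneTree],
                                    clade_leaves: Iterable[str],
                                    tax: TaxonomyMap,
                                    thr: GroupThresholds | None = None
                                    ) -> ConfigurationProfile:
    """Classify a clade in every bootstrap replicate and summarize.

    Frequencies sum to 1 over all labels (paraphyletic replicates included).
    Modal ties are broken by specificity: group-related, then three-domain,
    then domain-related, then unclear, then paraphyletic; within group-related,
    alphabetically.
    """
    if not bootstrap_trees:
        raise ConfigurationError("need at least one bootstrap tree")
    thr = thr or GroupThresholds.default()
    clade = frozenset(clade_leaves)
    counts: Counter = Counter()
    labels: dict[tuple, ConfigurationLabel] = {}
    for rep in bootstrap_trees:
        label = classify_configuration(rep, clade, tax, thr)
        counts[label.key] += 1
        labels.setdefault(label.key, ConfigurationLabel(label.kind, label.group))
    n = len(bootstrap_trees)
    freqs = {key: c / n for key, c in counts.items()}
    top = max(freqs.values())
    tied = sorted((key for key, f in freqs.items() if f == top),
                  key=_label_sort_key)
    if len(tied) > 1:
        logger.info("modal configuration tie among %s; keeping %s",
                    [f"{k}({g})" if g else k for k, g in tied], tied[0])
    modal = labels[tied[0]]
    group_fractions = {group: f for (kind, group), f in freqs.items()
                       if kind == GROUP_RELATED}
    return ConfigurationProfile(frequencies=freqs, modal=modal,
                                group_fractions=group_fractions,
                                n_replicates=n)
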