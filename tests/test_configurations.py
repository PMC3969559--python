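"""Configuration classification: thresholds, archetypes, modal profiles."""

import numpy as np
import pytest

from lecatrace.configurations import (ARCHAEAL_DOMAIN_RELATED,
                                      BACTERIAL_DOMAIN_RELATED,
                                      GROUP_RELATED, PARAPHYLETIC,
                                      THREE_DOMAIN, UNCLEAR,
                                      ConfigurationError,
                                      GroupThresholds,
                                      bootstrap_configuration_profile,
                                      classify_configuration, classify_naive)
from lecatrace.trees import parse_newick

from conftest import build_taxonomy


def chain(labels):
    if len(labels) == 1:
        return labels[0] + ":1"
    return f"({labels[0]}:1,{chain(labels[1:])}:1)"


def tax_of(**kinds):
    """kinds: prefix=(count, group, domain[, supergroup])."""
    spec = {}
    for prefix, fields in kinds.items():
        count, group, domain = fields[:3]
        supergroup = fields[3] if len(fields) > 3 else "NA"
        for i in range(1, count + 1):
            spec[f"{prefix}{i}"] = (f"{prefix}sp{i}", group, domain,
                                    supergroup)
    return build_taxonomy(spec)


class TestGroupThresholds:
    def test_half_is_ceiling_of_half_the_sampling(self):
        thr = GroupThresholds.default()
        assert thr.resolved("Actinobacteria") == 8      # 15 sampled
        assert thr.resolved("Alphaproteobacteria") == 5  # 10 sampled
        assert thr.resolved("Euryarchaeota") == 13       # 25 sampled

    def test_never_groups_cannot_be_assigned(self):
        thr = GroupThresholds.default()
        for group in ("Fusobacteria", "Thaumarchaeota", "Korarchaeota"):
            assert thr.resolved(group) is None

    def test_fixed_thresholds(self):
        thr = GroupThresholds.default()
        assert thr.resolved("Acidobacteria") == 3
        assert thr.resolved("Chlorobi") == 4

    def test_yaml_overrides(self, tmp_path):
        path = tmp_path / "thr.yaml"
        path.write_text(
            "domain_min: 5\n"
            "groups:\n  Alphaproteobacteria: {sampled: 10, threshold: 9}\n")
        thr = GroupThresholds.from_yaml(path)
        assert thr.resolved("Alphaproteobacteria") == 9
        assert thr.domain_min == 5
        assert thr.resolved("Chlorobi") == 4  # untouched default

    def test_unknown_group_is_error(self):
        with pytest.raises(ConfigurationError, match="no threshold"):
            GroupThresholds.default().resolved("Atlantis")


ALPHA_NESTED = ("(((A1:1,A2:1):1,((E1:1,E2:1):1,(A3:1,(A4:1,(A5:1,A6:1):1):1"
                "):1):1):1,(C1:1,(C2:1,C3:1):1):1);")


class TestClassifyConfiguration:
    def test_group_related_when_nested_in_rich_group(self):
        """Eukaryote clan inside a clan of 6 alphaproteobacterial species."""
        tax = tax_of(A=(6, "Alphaproteobacteria", "Bacteria"),
                     C=(3, "Cyanobacteria", "Bacteria"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        label = classify_configuration(parse_newick(ALPHA_NESTED),
                                       {"E1", "E2"}, tax)
        assert label.kind == GROUP_RELATED
        assert label.group == "Alphaproteobacteria"
        clan, n_species = label.evidence
        assert n_species == 6 and {"E1", "E2"} <= clan

    def test_isolated_sister_does_not_name_its_group(self):
        """A single transferred sequence as sister: bacterial-domain-related
        by configurations, its own group by the naive criterion."""
        tax = tax_of(G=(6, "Gammaproteobacteria", "Bacteria"),
                     C=(5, "Cyanobacteria", "Bacteria"),
                     D=(1, "Deltaproteobacteria", "Bacteria"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick(
            "((((E1:1,E2:1):1,D1:1):1," + chain([f"G{i}" for i in
                                                 range(1, 7)]) + ":1):1,"
            + chain([f"C{i}" for i in range(1, 6)]) + ":1);")
        clade = {"E1", "E2"}
        label = classify_configuration(tree, clade, tax)
        assert label.kind == BACTERIAL_DOMAIN_RELATED
        assert classify_naive(tree, clade, tax) == "Deltaproteobacteria"

    def test_three_domain_configuration(self):
        tax = tax_of(B=(12, "Cyanobacteria", "Bacteria"),
                     A=(11, "Euryarchaeota", "Archaea"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        nwk = ("(" + chain([f"B{i}" for i in range(1, 13)]) + ":1,("
               + chain([f"A{i}" for i in range(1, 12)])
               + ":1,(E1:1,E2:1):1):1);")
        label = classify_configuration(parse_newick(nwk), {"E1", "E2"}, tax)
        assert label.kind == THREE_DOMAIN

    def test_three_domain_needs_ten_species_per_domain(self):
        tax = tax_of(B=(12, "Cyanobacteria", "Bacteria"),
                     A=(6, "Euryarchaeota", "Archaea"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        nwk = ("(" + chain([f"B{i}" for i in range(1, 13)]) + ":1,("
               + chain([f"A{i}" for i in range(1, 7)])
               + ":1,(E1:1,E2:1):1):1);")
        label = classify_configuration(parse_newick(nwk), {"E1", "E2"}, tax)
        assert label.kind == UNCLEAR

    def test_mixed_domains_are_unclear(self):
        tax = tax_of(B=(4, "Cyanobacteria", "Bacteria"),
                     A=(4, "Euryarchaeota", "Archaea"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick(
            "(B1:1,((A1:1,(B2:1,(A2:1,(E1:1,E2:1):1):1):1):1,"
            "(B3:1,(A3:1,(B4:1,A4:1):1):1):1):1);")
        label = classify_configuration(tree, {"E1", "E2"}, tax)
        assert label.kind == UNCLEAR

    def test_paraphyletic_representatives(self):
        tax = tax_of(B=(4, "Cyanobacteria", "Bacteria"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick("((E1:1,B1:1):1,(E2:1,(B2:1,(B3:1,B4:1):1):1):1);")
        label = classify_configuration(tree, {"E1", "E2"}, tax)
        assert label.kind == PARAPHYLETIC

    def test_group_below_threshold_falls_back_to_domain(self):
        # nested among 2 Chlorobi species (threshold 4) inside a bacterial
        # context of >= 10 species
        tax = tax_of(H=(2, "Chlorobi", "Bacteria"),
                     G=(9, "Gammaproteobacteria", "Bacteria"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick(
            "((H1:1,((E1:1,E2:1):1,H2:1):1):1,"
            + chain([f"G{i}" for i in range(1, 10)]) + ":1);")
        label = classify_configuration(tree, {"E1", "E2"}, tax)
        assert label.kind == BACTERIAL_DOMAIN_RELATED
        _, n_species = label.evidence
        assert n_species == 11

    def test_never_group_falls_back_to_domain(self):
        tax = tax_of(F=(8, "Fusobacteria", "Bacteria"),
                     G=(4, "Gammaproteobacteria", "Bacteria"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick(
            "((F1:1,((E1:1,E2:1):1,(F2:1,(F3:1,(F4:1,(F5:1,(F6:1,(F7:1,F8:1)"
            ":1):1):1):1):1):1):1):1," + chain(["G1", "G2", "G3", "G4"])
            + ":1);")
        label = classify_configuration(tree, {"E1", "E2"}, tax)
        assert label.kind == BACTERIAL_DOMAIN_RELATED

    def test_archaeal_domain_related_when_nested_deep_in_archaea(self):
        tax = tax_of(B=(12, "Cyanobacteria", "Bacteria"),
                     A=(11, "Euryarchaeota", "Archaea"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        nwk = ("(" + chain([f"B{i}" for i in range(1, 13)]) + ":1,(A1:1,("
               + "(E1:1,E2:1):1," + chain([f"A{i}" for i in range(2, 12)])
               + ":1):1):1);")
        label = classify_configuration(parse_newick(nwk), {"E1", "E2"}, tax)
        assert label.kind == ARCHAEAL_DOMAIN_RELATED

    def test_missing_leaf_in_taxonomy_is_named(self):
        tax = tax_of(B=(3, "Cyanobacteria", "Bacteria"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick("((E1:1,E2:1):1,(B1:1,(B2:1,GHOST:1):1):1);")
        with pytest.raises(Exception, match="GHOST"):
            classify_configuration(tree, {"E1", "E2"}, tax)

    def test_deterministic_across_runs(self):
        tax = tax_of(A=(6, "Alphaproteobacteria", "Bacteria"),
                     C=(3, "Cyanobacteria", "Bacteria"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick(ALPHA_NESTED)
        labels = {classify_configuration(tree, {"E1", "E2"}, tax)
                  for _ in range(5)}
        assert len(labels) == 1


def brute_force_classify(tree, clade, tax, thr):
    """Independent oracle: enumerate every clan side explicitly and apply the
    configuration rules literally."""
    clade = frozenset(clade)
    sides = set()
    for b in tree.bipartitions(include_trivial=True):
        sides |= b.sides
    sides.add(tree.leaves)
    if clade != tree.leaves and clade not in sides and len(clade) > 1:
        return PARAPHYLETIC, None
    base_parts = []
    tri_sides = [s for s in sides if clade <= s and s != clade]
    # parts around the base: maximal proper subsets of (side - clade)
    stem_side = min(tri_sides, key=len) if tri_sides else tree.leaves

    # reconstruct base parts by brute force: subtrees adjacent to the stem
    edge = tree.clan_edge(clade)
    base, into = edge
    if tree.is_leaf(base):
        base_parts = [frozenset((tree.label_of(base),))]
    else:
        base_parts = [tree.subtree_leaves(base, w)
                      for w in tree.neighbors(base) if w != into]

    def embedded(s):
        return sum(1 for p in base_parts if p & s) >= 2

    def candidates(taxon, level):
        out = []
        for side in sides:
            if not clade <= side:
                continue
            proks = [x for x in side if tax[x].is_prokaryote]
            if not proks:
                continue
            values = {getattr(tax[x], level) for x in proks}
            if values == {taxon} and embedded(side):
                out.append(side)
        return out

    groups = sorted({tax[x].group for x in tree.leaves
                     if tax[x].is_prokaryote})
    eligible = []
    for g in groups:
        threshold = thr.resolved(g)
        if threshold is None:
            continue
        for side in candidates(g, "group"):
            n_species = len({tax[x].species_id for x in side
                             if tax[x].is_prokaryote})
            if n_species >= threshold:
                eligible.append((len(side), g))
    if eligible:
        return GROUP_RELATED, min(eligible)[1]
    domains = []
    for d in ("Archaea", "Bacteria"):
        for side in candidates(d, "domain"):
            n_species = len({tax[x].species_id for x in side
                             if tax[x].domain == d})
            if n_species >= thr.domain_min:
                domains.append(d)
                break
    if len(domains) == 1:
        return (ARCHAEAL_DOMAIN_RELATED if domains[0] == "Archaea"
                else BACTERIAL_DOMAIN_RELATED), None
    by_domain = {}
    for x in tree.leaves:
        by_domain.setdefault(tax[x].domain, set()).add(x)
    if all(d in by_domain for d in ("Eukarya", "Archaea", "Bacteria")):
        mono = all(frozenset(by_domain[d]) in sides or by_domain[d] == tree.leaves
                   for d in ("Eukarya", "Archaea", "Bacteria"))
        rich = all(len({tax[x].species_id for x in by_domain[d]}) >= 10
                   for d in ("Archaea", "Bacteria"))
        if mono and rich:
            return THREE_DOMAIN, None
    return UNCLEAR, None


@pytest.mark.parametrize("seed", range(10))
def test_classifier_matches_brute_force_on_random_trees(seed):
    from conftest import random_tree
    rng = np.random.default_rng(700 + seed)
    tax = tax_of(A=(4, "Alphaproteobacteria", "Bacteria"),
                 C=(4, "Cyanobacteria", "Bacteria"),
                 R=(4, "Euryarchaeota", "Archaea"),
                 E=(2, "Fungi", "Eukarya", "Unikonts"))
    thr = GroupThresholds.default().with_overrides(
        {"Alphaproteobacteria": (4, 3), "Cyanobacteria": (4, 3),
         "Euryarchaeota": (4, 3)})
    thr = GroupThresholds(thr.groups, domain_min=4,
                          three_domain_min={"Archaea": 4, "Bacteria": 4})
    labels = ([f"A{i}" for i in range(1, 5)] + [f"C{i}" for i in range(1, 5)]
              + [f"R{i}" for i in range(1, 5)] + ["E1", "E2"])
    for trial in range(10):
        tree = random_tree(rng, labels)
        got = classify_configuration(tree, {"E1", "E2"}, tax, thr)
        kind, group = brute_force_classify(tree, {"E1", "E2"}, tax, thr)
        assert (got.kind, got.group) == (kind, group), tree.as_newick()


class TestNaive:
    def test_mixed_bacterial_sister(self):
        tax = tax_of(A=(2, "Alphaproteobacteria", "Bacteria"),
                     C=(2, "Cyanobacteria", "Bacteria"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick(
            "(((E1:1,E2:1):1,(A1:1,C1:1):1):1,(A2:1,C2:1):1);")
        assert classify_naive(tree, {"E1", "E2"}, tax) == "Bacteria"

    def test_mixed_domain_sister(self):
        tax = tax_of(A=(2, "Alphaproteobacteria", "Bacteria"),
                     R=(2, "Euryarchaeota", "Archaea"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick(
            "(((E1:1,E2:1):1,(A1:1,R1:1):1):1,(A2:1,R2:1):1);")
        assert classify_naive(tree, {"E1", "E2"}, tax) == "mixed"

    def test_paraphyletic_input_is_error(self):
        tax = tax_of(B=(2, "Cyanobacteria", "Bacteria"),
                     E=(2, "Fungi", "Eukarya", "Unikonts"))
        tree = parse_newick("((E1:1,B1:1):1,(E2:1,B2:1):1);")
        with pytest.raises(ConfigurationError):
            classify_naive(tree, {"E1", "E2"}, tax)


class TestBootstrapProfile:
    TAX = None

    def setup_method(self):
        self.tax = tax_of(A=(6, "Alphaproteobacteria", "Bacteria"),
                          C=(5, "Cyanobacteria", "Bacteria"),
                          E=(2, "Fungi", "Eukarya", "Unikonts"))
        self.nested = parse_newick(
            "(((A1:1,A2:1):1,((E1:1,E2:1):1,(A3:1,(A4:1,(A5:1,A6:1):1):1):1"
            "):1):1," + chain([f"C{i}" for i in range(1, 6)]) + ":1);")
        # eukaryotes scattered -> paraphyletic
        self.para = parse_newick(
            "(((A1:1,E1:1):1,((A2:1,E2:1):1,(A3:1,(A4:1,(A5:1,A6:1):1):1):1"
            "):1):1," + chain([f"C{i}" for i in range(1, 6)]) + ":1);")

    def test_unanimous_profile(self):
        profile = bootstrap_configuration_profile([self.nested] * 10,
                                                  {"E1", "E2"}, self.tax)
        assert profile.frequencies == {
            (GROUP_RELATED, "Alphaproteobacteria"): 1.0}
        assert profile.modal.group == "Alphaproteobacteria"
        assert profile.group_fractions == {"Alphaproteobacteria": 1.0}

    def test_majority_wins(self):
        trees = [self.nested] * 6 + [self.para] * 4
        profile = bootstrap_configuration_profile(trees, {"E1", "E2"},
                                                  self.tax)
        assert profile.modal.kind == GROUP_RELATED
        assert profile.frequency(PARAPHYLETIC) == pytest.approx(0.4)
        assert sum(profile.frequencies.values()) == pytest.approx(1.0)

    def test_tie_prefers_more_specific_label(self):
        trees = [self.nested] * 5 + [self.para] * 5
        profile = bootstrap_configuration_profile(trees, {"E1", "E2"},
                                                  self.tax)
        assert profile.modal.kind == GROUP_RELATED
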