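"""NBS, SGS, monophyly support, near-universal filter, SGS calibration."""

import itertools

import numpy as np
import pytest

from lecatrace.support import (SupportError, calibrate_sgs_threshold,
                               clade_support, jaccard, monophyly_support, nbs,
                               near_universal_filter, sgs)
from lecatrace.taxonomy import TaxonomyMap, TaxonRecord
from lecatrace.trees import parse_newick

from conftest import oracle_bipartition_sides

ML = "((E1:1,E2:1):1,(P1:1,(P2:1,(P3:1,P4:1):1):1):1);"
SAME_TRIPARTITION = "((P3:1,P4:1):1,(P2:1,(P1:1,(E1:1,E2:1):1):1):1);"
MOVED = "((E1:1,E2:1):1,(P2:1,(P1:1,(P3:1,P4:1):1):1):1);"
PARA = "((E1:1,P1:1):1,(E2:1,(P2:1,(P3:1,P4:1):1):1):1);"


def brute_force_nbs(ml_tree, replicates, clade):
    """Independent oracle: check the three bipartitions by exhaustive
    enumeration of each replicate's splits."""
    tri = ml_tree.tripartition_at_base(frozenset(clade))
    hits = 0
    for rep in replicates:
        sides = oracle_bipartition_sides(rep)
        sides |= {rep.leaves - s for s in sides}
        if all(part in sides for part in tri.parts):
            hits += 1
    return 100.0 * hits / len(replicates)


def brute_force_sgs(replicates, clade):
    """Independent oracle: explicit double loop over replicate pairs."""
    from conftest import oracle_sister
    sisters = []
    for rep in replicates:
        if not rep.is_clan(frozenset(clade)):
            sisters.append(None)
        else:
            sisters.append(oracle_sister(rep, frozenset(clade)))
    n = len(sisters)
    total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        if sisters[i] is None or sisters[j] is None:
            continue
        total += jaccard(sisters[i], sisters[j])
    return 2.0 * total / (n * (n - 1))


class TestNBS:
    def test_identical_replicates_give_100(self):
        ml = parse_newick(ML)
        assert nbs(ml, [parse_newick(ML)] * 10, {"E1", "E2"}) == 100.0

    def test_direct_count(self):
        ml = parse_newick(ML)
        reps = [parse_newick(s) for s in (ML, SAME_TRIPARTITION, MOVED, PARA)]
        assert nbs(ml, reps, {"E1", "E2"}) == 50.0

    def test_always_paraphyletic_gives_0(self):
        ml = parse_newick(ML)
        assert nbs(ml, [parse_newick(PARA)] * 5, {"E1", "E2"}) == 0.0

    def test_clade_must_be_clan_of_ml_tree(self):
        ml = parse_newick(ML)
        with pytest.raises(Exception):
            nbs(ml, [parse_newick(ML)], {"E1", "P1"})

    def test_leafset_mismatch_is_hard_error(self):
        ml = parse_newick(ML)
        other = parse_newick("((E1:1,E2:1):1,(P1:1,P9:1):1);")
        with pytest.raises(SupportError, match="leaf set"):
            nbs(ml, [other], {"E1", "E2"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        from conftest import random_tree
        rng = np.random.default_rng(800 + seed)
        labels = ["E1", "E2"] + [f"P{i}" for i in range(6)]
        ml = parse_newick(
            "((E1:1,E2:1):1,(P0:1,(P1:1,(P2:1,(P3:1,(P4:1,P5:1):1):1):1):1)"
            ":1);")
        reps = [random_tree(rng, labels) for _ in range(15)]
        assert nbs(ml, reps, {"E1", "E2"}) == pytest.approx(
            brute_force_nbs(ml, reps, {"E1", "E2"}))


class TestSGS:
    def test_absolute_stability_is_one(self):
        reps = [parse_newick(ML)] * 8
        assert sgs(reps, {"E1", "E2"}) == 1.0

    def test_complete_disjunction_is_zero(self):
        # sister sets {P1} and {P2} alternate and never overlap... a truly
        # pairwise-disjoint ensemble needs distinct singleton sisters
        a = "((E1:1,E2:1):1,(P1:1,(P2:1,(P3:1,P4:1):1):1):1);"   # sister P1
        b = "((E1:1,E2:1):1,(P2:1,(P1:1,(P3:1,P4:1):1):1):1);"   # sister P2
        c = "((E1:1,E2:1):1,(P3:1,(P1:1,(P2:1,P4:1):1):1):1);"   # sister P3
        reps = [parse_newick(s) for s in (a, b, c)]
        assert sgs(reps, {"E1", "E2"}) == 0.0

    def test_worked_example_five_ninths(self):
        # sister sets {P1,P2}, {P1,P2}, {P1,P3}: mean of (1, 1/3, 1/3)
        ab = "((E1:1,E2:1):1,((P1:1,P2:1):1,(P3:1,P4:1):1):1);"
        ac = "((E1:1,E2:1):1,((P1:1,P3:1):1,(P2:1,P4:1):1):1);"
        reps = [parse_newick(ab), parse_newick(ab), parse_newick(ac)]
        assert sgs(reps, {"E1", "E2"}) == pytest.approx(5.0 / 9.0)

    def test_paraphyletic_replicates_contribute_zero(self):
        reps = [parse_newick(ML), parse_newick(ML), parse_newick(PARA)]
        assert sgs(reps, {"E1", "E2"}) == pytest.approx(1.0 / 3.0)

    def test_needs_two_replicates(self):
        with pytest.raises(SupportError):
            sgs([parse_newick(ML)], {"E1", "E2"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_double_loop(self, seed):
        from conftest import random_tree
        rng = np.random.default_rng(900 + seed)
        labels = ["E1", "E2"] + [f"P{i}" for i in range(6)]
        reps = [random_tree(rng, labels) for _ in range(20)]
        assert sgs(reps, {"E1", "E2"}) == pytest.approx(
            brute_force_sgs(reps, {"E1", "E2"}))

    @pytest.mark.parametrize("seed", range(3))
    def test_invariant_to_consistent_relabeling(self, seed):
        from conftest import random_tree
        rng = np.random.default_rng(950 + seed)
        labels = ["E1", "E2"] + [f"P{i}" for i in range(5)]
        reps = [random_tree(rng, labels) for _ in range(10)]
        value = sgs(reps, {"E1", "E2"})
        mapping = {lab: f"X_{lab}" for lab in labels}
        renamed = [parse_newick(_rename(t.as_newick(), mapping))
                   for t in reps]
        assert sgs(renamed, {"X_E1", "X_E2"}) == pytest.approx(value)


def _rename(newick, mapping):
    for old, new in sorted(mapping.items(), key=lambda kv: -len(kv[0])):
        newick = newick.replace(old, new)
    return newick


class TestCladeSupportReport:
    def test_report_fields(self):
        ml = parse_newick(ML)
        reps = [parse_newick(s) for s in (ML, ML, MOVED, PARA)]
        report = clade_support("c1", ml, reps, {"E1", "E2"})
        assert report.g_ml == {"P1"}
        assert report.nbs == 50.0
        assert 0.0 <= report.sgs <= 1.0
        assert report.sgs_percent == pytest.approx(100 * report.sgs)
        assert report.replicate_sisters[3] is None  # the paraphyletic one

    def test_sgs_pairwise_lower_bound_from_nbs(self):
        """Pairs of replicates that both match the ML tripartition have
        identical sisters, bounding SGS from below."""
        ml = parse_newick(ML)
        reps = [parse_newick(ML)] * 7 + [parse_newick(PARA)] * 3
        report = clade_support("c1", ml, reps, {"E1", "E2"})
        n, p = report.n_replicates, report.nbs / 100
        assert report.sgs >= p * (p * n - 1) / (n - 1) - 1e-9


class TestMonophylySupport:
    def test_single_leaf_and_full_set_are_always_clans(self):
        reps = [parse_newick(ML)] * 4
        assert monophyly_support(reps, {"P1"}) == 100.0
        assert monophyly_support(reps, set(parse_newick(ML).leaves)) == 100.0

    def test_direct_fraction(self):
        reps = [parse_newick(ML)] * 19 + [parse_newick(PARA)]
        assert monophyly_support(reps, {"E1", "E2"}) == 95.0

    def test_empty_taxon_is_error(self):
        with pytest.raises(SupportError):
            monophyly_support([parse_newick(ML)], set())


def reference_taxonomy(n_arch=39, n_bact=144):
    records = [TaxonRecord(f"a{i}", f"asp{i}", "Euryarchaeota", "Archaea",
                           "NA") for i in range(n_arch)]
    records += [TaxonRecord(f"b{i}", f"bsp{i}", "Cyanobacteria", "Bacteria",
                            "NA") for i in range(n_bact)]
    records.append(TaxonRecord("e0", "esp0", "Fungi", "Eukarya", "Unikonts"))
    return TaxonomyMap(records)


class TestNearUniversalFilter:
    def test_ceiling_rule_on_reference_sampling(self):
        tax = reference_taxonomy()
        present = {"Archaea": {f"asp{i}" for i in range(36)},
                   "Bacteria": {f"bsp{i}" for i in range(130)}}
        assert near_universal_filter(present, tax)  # ceil(35.1)=36, ceil(129.6)=130

    def test_one_species_short_fails(self):
        tax = reference_taxonomy()
        present = {"Archaea": {f"asp{i}" for i in range(35)},
                   "Bacteria": {f"bsp{i}" for i in range(144)}}
        assert not near_universal_filter(present, tax)

    def test_fraction_one_requires_everything(self):
        tax = reference_taxonomy(4, 5)
        full = {"Archaea": {f"asp{i}" for i in range(4)},
                "Bacteria": {f"bsp{i}" for i in range(5)}}
        assert near_universal_filter(full, tax, fraction=1.0)
        almost = {"Archaea": {f"asp{i}" for i in range(4)},
                  "Bacteria": {f"bsp{i}" for i in range(4)}}
        assert not near_universal_filter(almost, tax, fraction=1.0)

    def test_invalid_fraction_is_error(self):
        tax = reference_taxonomy(2, 2)
        with pytest.raises(SupportError):
            near_universal_filter({}, tax, fraction=0.0)


class TestCalibration:
    def test_all_correct_gives_zero_threshold(self):
        refs = [("c1", 90.0, "Alpha"), ("c2", 50.0, "Alpha")]
        result = calibrate_sgs_threshold(refs, "Alpha")
        assert result.threshold == 0.0 and result.usable

    def test_worked_example(self):
        refs = [("a", 90.0, "Alpha"), ("b", 70.0, "Alpha"),
                ("c", 50.0, "Alpha"), ("d", 45.0, "Gamma"),
                ("e", 30.0, "Mixed")]
        result = calibrate_sgs_threshold(refs, "Alpha")
        assert result.threshold == 45.0 and result.usable
        # every reference above the threshold is correctly assigned
        assert all(ok for _, s, _, ok in result.table if s > result.threshold)
        # table is sorted by decreasing SGS
        values = [s for _, s, _, _ in result.table]
        assert values == sorted(values, reverse=True)

    def test_single_correct_reference(self):
        result = calibrate_sgs_threshold([("c", 80.0, "Alpha")], "Alpha")
        assert result.threshold == 0.0 and result.usable

    def test_nothing_correct_is_flagged_unusable(self):
        refs = [("a", 90.0, "Gamma"), ("b", 70.0, "Mixed")]
        result = calibrate_sgs_threshold(refs, "Alpha")
        assert result.threshold == 90.0 and not result.usable

    def test_empty_reference_is_error(self):
        with pytest.raises(SupportError):
            calibrate_sgs_threshold([], "Alpha")
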