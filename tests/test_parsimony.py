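"""Multi-optimum parsimony engine, classification and event mapping."""

import dendropy
import numpy as np
import pytest

import intronpa as ip
from intronpa.parsimony import Event, EventHistory
from oracles import (brute_force_histories, maximal_absent_clades,
                     random_tree_newick)

P, A = "present", "absent"


def _pattern(tree, absent, unknown=()):
    labels = [l.taxon.label if l.taxon else l.label
              for l in tree.leaf_node_iter()]
    return {l: (A if l in absent else P) for l in labels
            if l not in unknown}


def _as_pairs(histories):
    return {(h.root_state, frozenset((e.kind, e.clade) for e in h.events))
            for h in histories}


class TestEnumeration:
    def test_two_cross_clade_absences_resolve_as_two_losses(self, grass6):
        hists = ip.enumerate_min_histories(
            grass6.tree, _pattern(grass6.tree, {"Zmay", "Bdis"}))
        assert len(hists) == 1
        h = hists[0]
        assert h.cost == 2 and h.losses == 2
        assert {e.clade for e in h.events} == {("Zmay",), ("Bdis",)}

    def test_within_panicoid_pair_ties_two_histories(self, grass6):
        hists = ip.enumerate_min_histories(
            grass6.tree, _pattern(grass6.tree, {"Zmay", "Sita"}))
        assert len(hists) == 2
        assert all(h.cost == 2 for h in hists)
        kinds = sorted(tuple(sorted(e.kind for e in h.events))
                       for h in hists)
        assert kinds == [("gain", "loss"), ("loss", "loss")]

    def test_all_present_gives_empty_history(self, grass6):
        hists = ip.enumerate_min_histories(
            grass6.tree, _pattern(grass6.tree, set()))
        assert len(hists) == 1 and hists[0].cost == 0

    def test_all_grasses_absent_ties_with_single_outgroup(self, grass6):
        # a lone outgroup cannot pin the root: stem loss ties with a
        # root-absent history that gains the intron in the outgroup
        hists = ip.enumerate_min_histories(
            grass6.tree, _pattern(grass6.tree, set(ip.GRASS_SPECIES)))
        assert len(hists) == 2
        assert {h.root_state for h in hists} == {P, A}

    def test_all_grasses_absent_is_stem_loss_with_deep_outgroups(self):
        full = ip.default_species_tree()
        hists = ip.enumerate_min_histories(
            full.tree, _pattern(full.tree, set(ip.GRASS_SPECIES)))
        assert len(hists) == 1
        (ev,) = hists[0].events
        assert ev.kind == "loss"
        assert set(ev.clade) == set(ip.GRASS_SPECIES)

    def test_no_known_leaf_is_an_error(self, grass6):
        with pytest.raises(ValueError):
            ip.enumerate_min_histories(grass6.tree, {})

    def test_matches_exhaustive_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(1000):
            n_leaves = int(rng.integers(4, 13))
            nwk = random_tree_newick(rng, n_leaves)
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            labels = [l.taxon.label for l in tree.leaf_node_iter()]
            pattern = {}
            for l in labels:
                r = rng.random()
                if r < 0.45:
                    pattern[l] = P
                elif r < 0.9:
                    pattern[l] = A
            if not any(s in (P, A) for s in pattern.values()):
                pattern[labels[0]] = A
            hists = ip.enumerate_min_histories(tree, pattern)
            expected, best = brute_force_histories(tree, pattern)
            assert _as_pairs(hists) == expected
            assert hists[0].cost == best
            n_checked += 1
        assert n_checked == 1000

    def test_every_history_replays_the_leaf_pattern(self, grass6):
        rng = np.random.default_rng(7)
        labels = grass6.leaf_labels()
        for _ in range(200):
            absent = {l for l in labels if rng.random() < 0.4}
            unknown = {l for l in labels if rng.random() < 0.15}
            pattern = _pattern(grass6.tree, absent, unknown)
            if not pattern:
                continue
            for h in ip.enumerate_min_histories(grass6.tree, pattern):
                states = h.replay(grass6.tree)
                for leaf, want in pattern.items():
                    assert states[leaf] == want

    def test_dollo_mode_equals_maximal_absent_clade_count(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n_leaves = int(rng.integers(4, 11))
            tree = dendropy.Tree.get(
                data=random_tree_newick(rng, n_leaves), schema="newick")
            labels = [l.taxon.label for l in tree.leaf_node_iter()]
            pattern = {l: (A if rng.random() < 0.5 else P) for l in labels}
            if not any(s == P for s in pattern.values()):
                pattern[labels[0]] = P
            assert (ip.min_dollo_losses(tree, pattern)
                    == maximal_absent_clades(tree, pattern))

    def test_present_outgroup_never_turns_resolved_losses_into_gains(
            self, grass5, grass6):
        # monotonicity over all 32 five-tip patterns
        for mask in range(32):
            absent = {s for i, s in enumerate(ip.GRASS_SPECIES)
                      if mask >> i & 1}
            before = ip.classify_group(ip.enumerate_min_histories(
                grass5.tree, _pattern(grass5.tree, absent)))
            after = ip.classify_group(ip.enumerate_min_histories(
                grass6.tree, _pattern(grass6.tree, absent)))
            if before.category in ("single_loss", "recurrent_loss"):
                assert after.category in ("single_loss", "recurrent_loss")
                assert after.history.cost <= max(before.history.cost, 1)


class TestClassification:
    def test_two_losses_in_non_sister_lineages_is_recurrent(self, grass6):
        cls = ip.classify_group(ip.enumerate_min_histories(
            grass6.tree, _pattern(grass6.tree, {"Sbic", "Osat"})))
        assert cls.category == "recurrent_loss"
        assert cls.n_events == 2

    def test_three_independent_losses_with_deep_outgroups(self):
        full = ip.default_species_tree()
        absent = {"Atha", "Zmay", "Sbic", "Bdis"}
        cls = ip.classify_group(ip.enumerate_min_histories(
            full.tree, _pattern(full.tree, absent)))
        assert cls.category == "recurrent_loss"
        assert cls.n_events == 3
        clades = sorted(e.clade for e in cls.history.events)
        assert clades == [("Atha",), ("Bdis",), ("Sbic", "Zmay")]

    def test_tied_histories_classify_unresolved(self, grass6):
        cls = ip.classify_group(ip.enumerate_min_histories(
            grass6.tree, _pattern(grass6.tree, {"Zmay", "Sita"})))
        assert cls.category == "unresolved"

    def test_empty_history_set_is_an_error(self):
        with pytest.raises(ValueError):
            ip.classify_group([])

    def test_mixed_event_order_labels(self, grass6):
        # loss on the Panicoid stem then regain in sorghum
        h = EventHistory(P, frozenset({
            Event("loss", ("Sbic", "Sita", "Zmay")),
            Event("gain", ("Sbic",))}))
        cls = ip.classify_group([h])
        assert cls.category == "mixed"
        assert cls.mixed_order == "loss_then_gain"


def _gtree(nwk):
    return dendropy.Tree.get(data=nwk, schema="newick",
                             preserve_underscores=True)


class TestParalogCollapse:
    species_of = {"Osat_c1_g1": "Osat", "Osat_c1_g2": "Osat",
                  "Zmay_c1_g1": "Zmay", "Sbic_c1_g1": "Sbic",
                  "Atha_c1_g1": "Atha"}
    nwk = ("(((Osat_c1_g1,Osat_c1_g2),(Zmay_c1_g1,Sbic_c1_g1)),"
           "Atha_c1_g1);")

    def _classify(self, absent):
        tree = _gtree(self.nwk)
        pattern = {l: (A if l in absent else P) for l in self.species_of}
        cls = ip.classify_group(ip.enumerate_min_histories(tree, pattern))
        return tree, cls

    def test_loss_shared_by_tandem_pair_counts_once(self):
        tree, cls = self._classify({"Osat_c1_g1", "Osat_c1_g2"})
        assert cls.category == "single_loss"
        assert ip.collapse_paralog_events(cls, tree, self.species_of) == 1

    def test_loss_in_one_paralog_counts_once(self):
        tree, cls = self._classify({"Osat_c1_g1"})
        assert ip.collapse_paralog_events(cls, tree, self.species_of) == 1

    def test_losses_in_different_species_do_not_collapse(self):
        tree, cls = self._classify({"Osat_c1_g1", "Zmay_c1_g1"})
        assert cls.category == "recurrent_loss"
        assert ip.collapse_paralog_events(cls, tree, self.species_of) == 2

    def test_defensive_merge_of_sibling_terminal_events(self):
        tree = _gtree(self.nwk)
        h = EventHistory(P, frozenset({
            Event("loss", ("Osat_c1_g1",)), Event("loss", ("Osat_c1_g2",))}))
        cls = ip.GroupClassification("recurrent_loss", [h])
        assert ip.collapse_paralog_events(cls, tree, self.species_of) == 1


class TestSpeciesBranchMapping:
    def test_terminal_and_stem_events_map_to_named_branches(self, grass6):
        sof = {"Zmay_c1_g1": "Zmay", "Sbic_c1_g1": "Sbic",
               "Sita_c1_g1": "Sita", "Bdis_c1_g1": "Bdis",
               "Osat_c1_g1": "Osat", "Atha_c1_g1": "Atha"}
        h = EventHistory(P, frozenset({
            Event("loss", ("Zmay_c1_g1",)),
            Event("loss", ("Sbic_c1_g1", "Zmay_c1_g1"))}))
        mapped, unmappable = ip.assign_events_to_species_branches(
            h, sof, grass6)
        assert sorted(mapped) == [("Andropogoneae", "loss"), ("Zmay", "loss")]
        assert unmappable == []

    def test_tree_conflict_is_flagged_unmappable(self, grass6):
        sof = {"Zmay_c1_g1": "Zmay", "Sbic_c1_g1": "Sbic",
               "Sita_c1_g1": "Sita", "Bdis_c1_g1": "Bdis",
               "Osat_c1_g1": "Osat"}
        h = EventHistory(P, frozenset({
            Event("loss", ("Osat_c1_g1", "Zmay_c1_g1"))}))
        mapped, unmappable = ip.assign_events_to_species_branches(
            h, sof, grass6)
        assert mapped == [] and len(unmappable) == 1


class TestAugmentation:
    def test_ambiguous_bep_event_resolves_with_banana(self, grass5):
        absent = {"Bdis", "Osat"}
        before = ip.classify_group(ip.enumerate_min_histories(
            grass5.tree, _pattern(grass5.tree, absent)))
        assert before.category == "unresolved"
        aug = _gtree("((((Zmay,Sbic),Sita),(Bdis,Osat)),Muca);")
        pattern = _pattern(aug, absent)
        res = ip.augment_with_outgroups(before, aug, pattern)
        assert res.augmented.category == "single_loss"
        assert res.transition == "unresolved->single_loss"

    def test_recurrent_gain_flips_to_recurrent_loss_with_deep_outgroups(
            self, grass6):
        absent = {"Sita", "Bdis", "Atha"}
        before = ip.classify_group(ip.enumerate_min_histories(
            grass6.tree, _pattern(grass6.tree, absent)))
        assert before.category == "recurrent_gain"
        full = ip.default_species_tree()
        res = ip.augment_with_outgroups(
            before, full.tree, _pattern(full.tree, absent))
        assert res.augmented.category == "recurrent_loss"
        assert res.augmented.history.losses == 3

    def test_all_unknown_outgroup_changes_nothing(self, grass6):
        absent = {"Sbic", "Osat"}
        before = ip.classify_group(ip.enumerate_min_histories(
            grass6.tree, _pattern(grass6.tree, absent)))
        full = ip.default_species_tree()
        pattern = _pattern(full.tree, absent,
                           unknown={"Muca", "Smoe", "Ppat"})
        res = ip.augment_with_outgroups(before, full.tree, pattern)
        assert res.augmented.category == before.category == "recurrent_loss"

    def test_lost_boundary_keeps_original_classification(self, grass6):
        before = ip.classify_group(ip.enumerate_min_histories(
            grass6.tree, _pattern(grass6.tree, {"Zmay"})))
        res = ip.augment_with_outgroups(before, None, None)
        assert res.boundary_lost and res.augmented is None


class TestProcessedCopies:
    nwk = "((A,B),(C,D));"
    genes = ["A", "B", "C", "D"]

    def _groups(self, n, absent_clade=("C", "D"), absent_in=None):
        groups = []
        for j in range(n):
            states = {g: "present" for g in self.genes}
            for g in (absent_in if absent_in is not None else absent_clade):
                states[g] = "absent"
            groups.append(ip.IntronGroup("c1", 100 + 30 * j, states, {}))
        return groups

    def test_syntenic_intronless_clade_is_cdna_conversion(self):
        cands = ip.detect_processed_copy_clades(
            "c1", _gtree(self.nwk), self._groups(9),
            {"C": True, "D": True})
        (cand,) = cands
        assert cand.clade == ("C", "D")
        assert cand.n_ancestral_introns == 9
        assert cand.label == "cDNA_conversion"

    def test_non_syntenic_clade_is_retroposition(self):
        (cand,) = ip.detect_processed_copy_clades(
            "c1", _gtree(self.nwk), self._groups(9),
            {"C": True, "D": False})
        assert cand.label == "retroposition"

    def test_clade_missing_seven_of_eight_introns_is_not_flagged(self):
        groups = self._groups(7) + self._groups(1, absent_in=("C",))
        cands = ip.detect_processed_copy_clades(
            "c1", _gtree(self.nwk), groups, {})
        assert all(set(c.clade) != {"C", "D"} for c in cands)
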