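"""Weighted parsimony, Dollo concordance, and the event funnel."""

import pytest

from domgain.gain_inference import (
    GainEvent,
    assign_age_group,
    dollo_concordance,
    exclude_leaf_gains,
    group_simultaneous_gains,
    infer_family_gains,
    make_gain_event,
    sankoff_reconstruct,
    select_representative,
    similarity_exclusion,
    StateChange,
)
from domgain.io_model import DomainHit, parse_gene_tree

from conftest import (
    make_family,
    random_binary_tree,
    random_protein,
    sankoff_cost_oracle,
)


def presence_of(tree, states):
    from domgain.gain_inference import PresenceMatrix

    return PresenceMatrix(
        genes=tuple(tree.leaf_names()),
        characters=("PF1",),
        data={(g, "PF1"): s for g, s in states.items() if s},
    )


class TestSankoff:
    def test_conserved_character_yields_no_events(self):
        tree = parse_gene_tree(
            "((A:1[&&NHX:S=x],B:1[&&NHX:S=x]):1,C:1[&&NHX:S=x]);"
        )
        rec = sankoff_reconstruct(
            tree, presence_of(tree, {"A": 1, "B": 1, "C": 1}), "PF1"
        )
        assert rec.events == []
        assert rec.states[tree.root.name] == 1

    def test_caterpillar_single_gain_beats_three_losses(self):
        """5-leaf caterpillar with only A,B present: one gain (cost 2) on the
        edge into their ancestor beats three losses (cost 3)."""
        tree = parse_gene_tree(
            "((((A:1[&&NHX:S=x],B:1[&&NHX:S=x])ab:1,C:1[&&NHX:S=x]):1,"
            "D:1[&&NHX:S=x]):1,E:1[&&NHX:S=x]);"
        )
        states = {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0}
        rec = sankoff_reconstruct(tree, presence_of(tree, states), "PF1")
        gains = [e for e in rec.events if e.kind == "gain"]
        assert rec.cost == 2.0
        assert len(gains) == 1 and gains[0].node_name == "ab"
        assert sankoff_cost_oracle(tree, states, 2.0, 1.0) == 2.0

    def test_balanced_tree_one_loss_beats_one_gain(self):
        """((A,B),(C,D)) with A,B present: ancestral presence plus one loss
        (cost 1) beats a gain (cost 2); no gain is called."""
        tree = parse_gene_tree(
            "((A:1[&&NHX:S=x],B:1[&&NHX:S=x]):1,"
            "(C:1[&&NHX:S=x],D:1[&&NHX:S=x])cd:1);"
        )
        states = {"A": 1, "B": 1, "C": 0, "D": 0}
        rec = sankoff_reconstruct(tree, presence_of(tree, states), "PF1")
        assert rec.cost == 1.0
        assert [e.kind for e in rec.events] == ["loss"]
        assert rec.events[0].node_name == "cd"
        assert sankoff_cost_oracle(tree, states, 2.0, 1.0) == 1.0

    def test_absent_character_returns_empty(self):
        tree = parse_gene_tree("(A:1[&&NHX:S=x],B:1[&&NHX:S=x]);")
        rec = sankoff_reconstruct(tree, presence_of(tree, {}), "PF1")
        assert rec.events == [] and rec.cost == 0.0

    def test_cost_matches_enumeration_oracle_on_random_trees(self, rng):
        """Property: Sankoff total cost equals exhaustive enumeration over
        all internal labellings, on random trees of up to 8 leaves."""
        for _ in range(300):
            n = int(rng.integers(2, 9))
            tree = random_binary_tree(rng, n)
            states = {name: int(rng.integers(0, 2)) for name in tree.leaf_names()}
            rec = sankoff_reconstruct(tree, presence_of(tree, states), "PF1")
            assert rec.cost == sankoff_cost_oracle(tree, states, 2.0, 1.0)

    def test_tie_between_gain_and_losses_prefers_gain_free(self):
        """(((A,B),C),D) with A,B present: one gain (cost 2) ties two losses
        (cost 2); the gain-averse tie rule reports the loss labelling."""
        tree = parse_gene_tree(
            "(((A:1[&&NHX:S=x],B:1[&&NHX:S=x])ab:1,C:1[&&NHX:S=x]):1,"
            "D:1[&&NHX:S=x]);"
        )
        states = {"A": 1, "B": 1, "C": 0, "D": 0}
        rec = sankoff_reconstruct(tree, presence_of(tree, states), "PF1")
        assert rec.cost == 2.0
        assert sankoff_cost_oracle(tree, states, 2.0, 1.0) == 2.0
        assert all(e.kind == "loss" for e in rec.events)
        assert len(rec.events) == 2


class TestDolloAndLeafFilters:
    def _gain(self, char, node):
        return StateChange("fam1", char, node, "gain")

    def test_single_gain_retained_two_gains_discarded(self):
        events = [self._gain("PF1", "n1"), self._gain("PF1", "n2"),
                  self._gain("PF2", "n3")]
        kept = dollo_concordance(events)
        assert [e.character_id for e in kept] == ["PF2"]

    def test_rule_is_per_character(self):
        events = [self._gain("PF1", "n1"), self._gain("PF2", "n2")]
        assert len(dollo_concordance(events)) == 2

    def test_losses_untouched(self):
        events = [
            self._gain("PF1", "n1"), self._gain("PF1", "n2"),
            StateChange("fam1", "PF1", "n3", "loss"),
        ]
        kept = dollo_concordance(events)
        assert [e.kind for e in kept] == ["loss"]

    def test_leaf_gains_dropped_internal_kept(self):
        tree = parse_gene_tree(
            "((A:1[&&NHX:S=x],B:1[&&NHX:S=x])ab:1,C:1[&&NHX:S=x]);"
        )
        events = [self._gain("PF1", "A"), self._gain("PF2", "ab")]
        kept = exclude_leaf_gains(events, tree)
        assert [e.node_name for e in kept] == ["ab"]


class TestRepresentativeSelection:
    def _family(self, rng):
        tree = parse_gene_tree(
            "(((H:1[&&NHX:S=human],Z:1[&&NHX:S=zebrafish])hz:1,"
            "O1:1[&&NHX:S=worm]):1,O2:1[&&NHX:S=sponge]);"
        )
        domain = random_protein(rng, 60)
        seqs = {
            "H": random_protein(rng, 50) + domain,
            "Z": random_protein(rng, 50) + domain,
            "O1": random_protein(rng, 110),
            "O2": random_protein(rng, 110),
        }
        hits = [
            DomainHit("H_t1", "PF1", 50, 110, 1e-20, 0.9),
            DomainHit("Z_t1", "PF1", 50, 110, 1e-20, 0.9),
        ]
        return make_family(tree, seqs, hits)

    def test_preferred_species_wins(self, rng):
        fam = self._family(rng)
        event = make_gain_event(
            fam, StateChange("fam1", "PF1", "hz", "gain")
        )
        assert select_representative(event, fam) == "H_t1"

    def test_rejected_when_no_quality_species(self, rng):
        fam = self._family(rng)
        event = make_gain_event(fam, StateChange("fam1", "PF1", "hz", "gain"))
        assert (
            select_representative(event, fam, quality_species={"mouse"}) is None
        )

    def test_rescued_only_hits_not_eligible(self, rng):
        fam = self._family(rng)
        for h in fam.hits:
            if h.sequence_id == "H_t1":
                h.provenance = "rescued"
        event = make_gain_event(fam, StateChange("fam1", "PF1", "hz", "gain"))
        assert select_representative(event, fam) == "Z_t1"


class TestSimilarityExclusion:
    def _family_with_identity(self, rng, n_identical):
        """Family where the gained 25-aa domain shares exactly
        ``n_identical`` aligned residues with the domain-lacking homolog."""
        tree = parse_gene_tree(
            "(((H:1[&&NHX:S=human],M:1[&&NHX:S=mouse])hm:1,"
            "O1:1[&&NHX:S=worm]):1,O2:1[&&NHX:S=sponge]);"
        )
        anc = random_protein(rng, 120)
        domain = random_protein(rng, 25)
        # homolog carries a same-length segment agreeing at exactly n positions
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        decoy = [
            alphabet[(alphabet.index(c) + 1) % 20] for c in domain
        ]  # differs everywhere
        for i in range(n_identical):
            decoy[i] = domain[i]
        rep = anc[:60] + domain + anc[60:]
        hom = anc[:60] + "".join(decoy) + anc[60:]
        seqs = {"H": rep, "M": rep, "O1": hom, "O2": hom}
        hits = [
            DomainHit("H_t1", "PF1", 60, 85, 1e-20, 0.9),
            DomainHit("M_t1", "PF1", 60, 85, 1e-20, 0.9),
        ]
        fam = make_family(tree, seqs, hits)
        event = make_gain_event(fam, StateChange("fam1", "PF1", "hm", "gain"))
        event.representative_transcript = "H_t1"
        return event, fam

    def test_sixteen_percent_rejected(self, rng):
        event, fam = self._family_with_identity(rng, 5)  # 5/25 = 20%
        assert similarity_exclusion(event, fam) is False

    def test_below_threshold_kept(self, rng):
        event, fam = self._family_with_identity(rng, 2)  # 8%
        assert similarity_exclusion(event, fam) is True

    def test_boundary_exactly_sixteen_percent_rejected(self, rng):
        event, fam = self._family_with_identity(rng, 4)  # 4/25 = 16%
        assert similarity_exclusion(event, fam) is False

    def test_vacuously_kept_without_lacking_sequences(self, rng):
        tree = parse_gene_tree("(A:1[&&NHX:S=human],B:1[&&NHX:S=human])ab;")
        domain = random_protein(rng, 40)
        seqs = {"A": domain, "B": domain}
        hits = [
            DomainHit("A_t1", "PF1", 0, 40, 1e-20, 0.9),
            DomainHit("B_t1", "PF1", 0, 40, 1e-20, 0.9),
        ]
        fam = make_family(tree, seqs, hits)
        event = make_gain_event(fam, StateChange("fam1", "PF1", "ab", "gain"))
        event.representative_transcript = "A_t1"
        assert similarity_exclusion(event, fam) is True


class TestGroupingAndAges:
    def _event(self, char, node, species=("human", "macaque")):
        return GainEvent(
            family_id="fam1",
            character_ids=(char,),
            node_name=node,
            parent_node_kind="speciation",
            descendant_genes=("g1", "g2"),
            descendant_species=species,
        )

    def test_same_node_characters_merge(self):
        merged = group_simultaneous_gains(
            [self._event("PF_preSET", "n1"), self._event("PF_SET", "n1")]
        )
        assert len(merged) == 1
        assert merged[0].character_ids == ("PF_SET", "PF_preSET")

    def test_sibling_nodes_stay_separate(self):
        merged = group_simultaneous_gains(
            [self._event("PF1", "n1"), self._event("PF1", "n2")]
        )
        assert len(merged) == 2

    def test_merged_count_never_exceeds_input(self, rng):
        events = [
            self._event(f"PF{i}", f"n{int(rng.integers(0, 5))}")
            for i in range(20)
        ]
        assert len(group_simultaneous_gains(events)) <= len(events)

    @pytest.mark.parametrize(
        "species,expected",
        [
            (("human", "macaque"), "primates"),
            (("human", "mouse"), "mammals"),
            (("human", "zebrafish"), "vertebrates"),
            (("human", "fruit_fly"), "bilateria"),
            (("human", "sea_anemone"), "animals"),
        ],
    )
    def test_smallest_containing_clade(self, species, expected):
        assert assign_age_group(self._event("PF1", "n1", species)) == expected

    def test_unknown_species_raises(self):
        with pytest.raises(ValueError, match="not in clade map"):
            assign_age_group(self._event("PF1", "n1", ("human", "martian")))


class TestFunnel:
    def test_stages_are_monotone_and_planted_gain_recovered(self, rng):
        from domgain.simulate import SimulationConfig, simulate_dataset

        ds = simulate_dataset(SimulationConfig(seed=5, n_families=4))
        for fam, truth in zip(ds.families, ds.truth):
            result = infer_family_gains(fam)
            counts = [result.stage_counts[s] for s in (
                "concordant_gains", "internal_node_gains",
                "with_representative", "after_similarity_exclusion",
                "grouped_events", "after_blacklist",
            )]
            assert counts == sorted(counts, reverse=True)
            assert any(
                e.node_name == truth.gain_node
                and truth.character_id in e.character_ids
                for e in result.events
            )
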