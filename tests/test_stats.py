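"""Summary statistics: distribution table, chi-square, enrichment, disorder."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from domgain.gain_inference import GainEvent
from domgain.io_model import DisorderTrack, DomainHit, parse_gene_tree
from domgain.mechanism_donor import ClassifiedEvent, DonorCall, MechanismCall
from domgain.stats_report import (
    duplication_enrichment,
    funnel_report,
    round_half_up_percent,
    summarize_distribution,
    terminal_enrichment_test,
)
from domgain.structure_classification import (
    CARBOXY,
    EXTENSION_ONLY,
    MIDDLE,
    MULTIPLE_NEW,
    StructureCall,
)

from conftest import make_family, random_protein


def classified(position, category, n_new=2, age="mammals", family="f",
               node="n", rep=None):
    return ClassifiedEvent(
        event=GainEvent(
            family_id=family, character_ids=("PF1",), node_name=node,
            parent_node_kind="speciation", descendant_genes=("g",),
            descendant_species=("human",), age_group=age,
            representative_transcript=rep,
        ),
        structure=StructureCall(position, category, n_new),
        donor=DonorCall(),
        mechanism=MechanismCall("unclassified"),
    )


class TestDistribution:
    def test_single_event_is_100_percent(self):
        table = summarize_distribution([classified(CARBOXY, MULTIPLE_NEW)])
        assert table["percent"].tolist() == [100.0]

    def test_percentages_sum_to_100(self):
        events = (
            [classified(CARBOXY, MULTIPLE_NEW)] * 3
            + [classified(MIDDLE, EXTENSION_ONLY, 0)] * 2
        )
        table = summarize_distribution(events)
        assert table["percent"].sum() == pytest.approx(100.0)
        assert table["count"].sum() == 5

    def test_empty_event_set_gives_empty_table(self):
        assert len(summarize_distribution([])) == 0

    def test_order_invariance(self):
        events = [classified(CARBOXY, MULTIPLE_NEW),
                  classified(MIDDLE, EXTENSION_ONLY, 0)]
        t1 = summarize_distribution(events)
        t2 = summarize_distribution(events[::-1])
        assert t1.equals(t2)


class TestChiSquare:
    def test_observed_equal_expected_gives_zero(self):
        res = terminal_enrichment_test([50, 50], [0.5, 0.5])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_statistic(self):
        # (90-50)^2/50 + (10-50)^2/50 = 64
        res = terminal_enrichment_test([90, 10], [0.5, 0.5])
        assert res.statistic == pytest.approx(64.0)

    def test_small_expected_count_warns(self):
        res = terminal_enrichment_test([6, 1], [0.6, 0.4])
        assert res.warning is not None

    def test_zero_expected_with_observed_undefined(self):
        res = terminal_enrichment_test([5, 5], [1.0, 0.0])
        assert math.isnan(res.statistic)
        assert res.warning and "undefined" in res.warning

    def test_matches_scipy_oracle_on_random_tables(self, rng):
        """p-values agree with scipy.stats.chisquare to 1e-10 relative."""
        for _ in range(200):
            counts = rng.integers(5, 200, size=2)
            p = rng.uniform(0.1, 0.9)
            props = [p, 1 - p]
            res = terminal_enrichment_test(list(counts), props)
            n = counts.sum()
            oracle = sps.chisquare(counts, f_exp=[q * n for q in props])
            assert res.statistic == pytest.approx(oracle.statistic, rel=1e-10)
            assert res.p_value == pytest.approx(oracle.pvalue, rel=1e-10, abs=0)


def _gain_event(kind):
    return GainEvent(
        family_id="f", character_ids=("PF1",), node_name="n",
        parent_node_kind=kind, descendant_genes=("g",),
        descendant_species=("human",),
    )


class TestDuplicationEnrichment:
    def _family(self, rng, dup_len, spec_len):
        # one duplication node and one speciation node with controlled
        # child branch lengths
        tree = parse_gene_tree(
            f"((A:{dup_len / 2}[&&NHX:S=human],B:{dup_len / 2}[&&NHX:S=human])"
            f"[&&NHX:D=Y]:{spec_len / 2},C:{spec_len / 2}[&&NHX:S=human])"
            "[&&NHX:D=N];"
        )
        seqs = {g: random_protein(rng, 30) for g in "ABC"}
        return make_family(tree, seqs, [])

    def test_arithmetic_of_branch_length_expectation(self, rng):
        """2 gains after duplication, 1 after speciation; duplication branch
        share 10, speciation 20 -> (2/1)/(10/20) = 4.0."""
        fam = self._family(rng, dup_len=10.0, spec_len=20.0)
        events = [_gain_event("duplication")] * 2 + [_gain_event("speciation")]
        res = duplication_enrichment(events, [fam])
        assert res.ratio_branch_length == pytest.approx(4.0)
        # node counts: 1 duplication, 1 speciation -> (2/1)/(1/1) = 2.0
        assert res.ratio_node_count == pytest.approx(2.0)

    def test_no_speciation_gains_flagged_infinite(self, rng):
        fam = self._family(rng, 10.0, 10.0)
        res = duplication_enrichment([_gain_event("duplication")], [fam])
        assert res.ratio_branch_length is None
        assert "infinite" in res.flag

    def test_no_duplication_nodes_flagged(self, rng):
        tree = parse_gene_tree(
            "(A:1[&&NHX:S=human],B:1[&&NHX:S=human])[&&NHX:D=N];"
        )
        fam = make_family(tree, {g: random_protein(rng, 30) for g in "AB"}, [])
        res = duplication_enrichment(
            [_gain_event("duplication"), _gain_event("speciation")], [fam]
        )
        assert res.ratio_branch_length is None
        assert res.flag is not None

    def test_uniform_gains_per_branch_length_give_enrichment_one(self, rng):
        """Stochastic null: gains planted uniformly per unit branch length,
        irrespective of node kind, give enrichment ~1 under the
        branch-length expectation (fixed seed, +-2 s.e.)."""
        from conftest import random_binary_tree

        families = []
        edges = []  # (family idx, node name, parent kind, length)
        for i in range(60):
            tree = random_binary_tree(rng, int(rng.integers(4, 9)),
                                      prefix=f"t{i}_g")
            fam = make_family(
                tree,
                {g: random_protein(rng, 20) for g in tree.leaf_names()},
                [],
            )
            families.append(fam)
            parents = tree.parent_map()
            for node in tree.root.walk():
                parent = parents[id(node)]
                if parent is None:
                    continue
                edges.append((parent.node_kind, node.branch_length))
        lengths = np.array([l for _, l in edges])
        probs = lengths / lengths.sum()
        n_gains = 400
        picks = rng.choice(len(edges), size=n_gains, p=probs)
        events = [
            _gain_event(
                "duplication" if edges[k][0] == "duplication" else "speciation"
            )
            for k in picks
        ]
        res = duplication_enrichment(events, families)
        gd = res.gains_after_duplication
        share = gd / n_gains
        se = math.sqrt(share * (1 - share) / n_gains)
        expected_share = (
            res.duplication_branch_length
            / (res.duplication_branch_length + res.speciation_branch_length)
        )
        # enrichment 1.0 within 2 s.e. of the binomial sampling noise
        assert abs(share - expected_share) <= 2 * se + 1e-9
        assert res.ratio_branch_length == pytest.approx(
            (share / (1 - share)) / (expected_share / (1 - expected_share))
        )


class TestDisorderSummary:
    def test_fractions_per_category(self, rng):
        from domgain.stats_report import disorder_summary

        tree = parse_gene_tree("(A:1[&&NHX:S=human],B:1[&&NHX:S=human]);")
        seq = random_protein(rng, 100)
        hits = [
            DomainHit("A_t1", "PF_gained", 0, 50, 1e-20, 0.9),
            DomainHit("A_t1", "PF_other", 50, 100, 1e-20, 0.9),
        ]
        fam = make_family(tree, {"A": seq, "B": seq}, hits)
        # 21 of 50 gained-domain residues disordered; other domain fully ordered
        scores = [0.9] * 21 + [0.1] * 29 + [0.1] * 50
        tracks = {"A_t1": DisorderTrack("A_t1", tuple(scores))}
        ce = classified(CARBOXY, EXTENSION_ONLY, 0, rep="A_t1")
        ce.event.character_ids = ("PF_gained",)
        ce.event.family_id = "fam1"
        out = disorder_summary([ce], {"fam1": fam}, tracks)
        assert out["gained_by_category"][EXTENSION_ONLY] == pytest.approx(42.0)
        assert out["other_domains"] == pytest.approx(0.0)

    def test_missing_track_skipped_with_note(self, rng):
        from domgain.stats_report import disorder_summary

        tree = parse_gene_tree("(A:1[&&NHX:S=human],B:1[&&NHX:S=human]);")
        seq = random_protein(rng, 60)
        fam = make_family(
            tree, {"A": seq, "B": seq},
            [DomainHit("A_t1", "PF1", 0, 30, 1e-20, 0.9)],
        )
        ce = classified(CARBOXY, EXTENSION_ONLY, 0, rep="A_t1")
        ce.event.family_id = "fam1"
        out = disorder_summary([ce], {"fam1": fam}, {})
        assert out["skipped_missing_track"] == ["A_t1"]


class TestFunnelReport:
    def test_ordered_with_deltas(self):
        table = funnel_report(
            {"concordant_gains": 10, "internal_node_gains": 7,
             "with_representative": 7, "after_similarity_exclusion": 5,
             "grouped_events": 5, "after_blacklist": 5}
        )
        assert table["events"].tolist() == [10, 7, 7, 5, 5, 5]
        assert table["removed"].tolist() == [0, 3, 0, 2, 0, 0]

    def test_non_monotone_counts_rejected(self):
        with pytest.raises(ValueError, match="more than its predecessor"):
            funnel_report({"concordant_gains": 3, "internal_node_gains": 5})

    def test_empty_funnel_all_zero(self):
        table = funnel_report({"concordant_gains": 0, "internal_node_gains": 0})
        assert table["events"].tolist() == [0, 0]


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (70.9, 71), (31.5, 32), (55.6, 56), (0.5, 1), (2.4, 2),
    ])
    def test_half_up(self, value, expected):
        assert round_half_up_percent(value) == expected
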