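"""Exon novelty, extension detection, phase symmetry, structure calls."""

import pytest

from domgain.io_model import ExonModel, Transcript
from domgain.structure_classification import (
    AMBIGUOUS,
    CARBOXY,
    EXTENSION_ONLY,
    MIDDLE,
    MULTIPLE_NEW,
    SINGLE_NEW,
    StructureCall,
    _is_novel,
    check_symmetric_phases,
    classify_gain_structure,
    detect_exon_extension,
    per_exon_homology,
)

from conftest import random_protein


def transcript(seq, exons, phases, tid="rep_t1"):
    return Transcript(
        transcript_id=tid,
        gene_id="rep",
        species="human",
        protein_sequence=seq,
        exon_model=ExonModel(tuple(exons), tuple(phases)),
    )


class TestNoveltyRule:
    @pytest.mark.parametrize(
        "length,unaligned,identity,novel",
        [
            (50, 0.96, 0.50, True),    # 85% unaligned clause
            (50, 0.85, 0.50, True),    # boundary: >= 0.85 passes
            (50, 0.84, 0.50, False),   # just below, identity too high
            (50, 0.10, 0.09, True),    # < 10% identity clause
            (50, 0.10, 0.10, False),   # boundary: identity must be < 0.10
            (50, 0.10, 0.35, False),   # fails both clauses
            (15, 0.10, 0.35, True),    # short exon: < 40% rule applies
            (20, 0.10, 0.39, True),    # boundary length: <= 20 residues
            (20, 0.10, 0.40, False),   # boundary identity for short exons
            (21, 0.10, 0.35, False),   # one residue longer: 10% rule again
        ],
    )
    def test_boundaries(self, cfg, length, unaligned, identity, novel):
        assert _is_novel(length, unaligned, identity, cfg) is novel


class TestPerExonHomology:
    def test_inserted_exon_flagged_novel_ancestral_not(self, rng):
        anc = random_protein(rng, 120)
        novel = random_protein(rng, 50)
        rep_seq = anc[:60] + novel + anc[60:]
        rep = transcript(rep_seq, [(0, 60), (60, 110), (110, 170)], (0, 1))
        table = per_exon_homology(rep, [anc])
        assert [e.novel for e in table] == [False, True, False]
        assert table[1].unaligned_fraction == 1.0

    def test_no_homologs_all_indeterminate(self, rng):
        rep = transcript(random_protein(rng, 100), [(0, 100)], ())
        table = per_exon_homology(rep, [])
        assert all(e.indeterminate for e in table)


class TestExtensionDetection:
    def _case(self, rng, boundary_identical, boundary_len=12, anc_exon=36):
        """Last exon = ancestral stretch + appended domain; the homolog
        agrees with the rep at ``boundary_identical`` of the first
        ``boundary_len`` ancestral positions of that exon."""
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        anc = random_protein(rng, 80 + anc_exon)
        domain = random_protein(rng, 60)
        rep_seq = anc + domain
        hom = list(anc)
        start_last = 80  # last exon starts here; domain starts at 80+anc_exon
        third = max(anc_exon // 3, 7)
        for i in range(start_last, start_last + third):
            if i - start_last >= boundary_identical:
                hom[i] = alphabet[(alphabet.index(hom[i]) + 1) % 20]
        # degrade the rest of the last-exon ancestral stretch as well so
        # identity comes only from the planted positions
        for i in range(start_last + third, start_last + anc_exon):
            hom[i] = alphabet[(alphabet.index(hom[i]) + 1) % 20]
        rep = transcript(
            rep_seq, [(0, 40), (40, 80), (80, 140 + anc_exon)], (0, 2)
        )
        gained = (80 + anc_exon, 140 + anc_exon)
        return rep, ["".join(hom)], gained

    def test_extension_at_30_percent(self, rng):
        # boundary third of 12, 4/12 identical = 33% >= 30%
        rep, homs, span = self._case(rng, boundary_identical=4)
        flags = detect_exon_extension(rep, homs, span)
        assert flags == {2: True}

    def test_below_30_percent_no_extension(self, rng):
        # 2/12 identical = 17%
        rep, homs, span = self._case(rng, boundary_identical=2)
        flags = detect_exon_extension(rep, homs, span)
        assert flags == {2: False}

    def test_boundary_shorter_than_7_skipped(self, rng):
        # 18-residue ancestral stretch: third = 6 < 7 -> minimum of 7 used;
        # a 6-residue outside region is skipped entirely
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        anc = random_protein(rng, 86)
        domain = random_protein(rng, 60)
        rep_seq = anc + domain
        rep = transcript(rep_seq, [(0, 40), (40, 80), (80, 146)], (0, 2))
        # only 6 residues of the last exon lie outside the domain
        gained = (86, 146)
        flags = detect_exon_extension(rep, [anc], gained)
        assert flags == {2: False}

    def test_exon_fully_inside_domain_not_tested(self, rng):
        anc = random_protein(rng, 80)
        novel = random_protein(rng, 50)
        rep = transcript(
            anc[:40] + novel + anc[40:],
            [(0, 40), (40, 90), (90, 130)],
            (0, 0),
        )
        flags = detect_exon_extension(rep, [anc], (40, 90))
        assert flags == {}


class TestSymmetricPhases:
    def test_equal_phases_symmetric(self, rng):
        rep = transcript(
            random_protein(rng, 120),
            [(0, 40), (40, 80), (80, 120)],
            (1, 1),
        )
        phases, flag = check_symmetric_phases(rep, (1, 1))
        assert phases == (1, 1) and flag is True

    def test_unequal_phases_not_symmetric(self, rng):
        rep = transcript(
            random_protein(rng, 120),
            [(0, 40), (40, 80), (80, 120)],
            (0, 2),
        )
        phases, flag = check_symmetric_phases(rep, (1, 1))
        assert phases == (0, 2) and flag is False

    def test_terminal_block_not_applicable(self, rng):
        rep = transcript(
            random_protein(rng, 120),
            [(0, 40), (40, 80), (80, 120)],
            (0, 0),
        )
        assert check_symmetric_phases(rep, (0, 0)) == (None, None)
        assert check_symmetric_phases(rep, None) == (None, None)


class TestClassifyGainStructure:
    def test_carboxy_terminal_multiple_new_exons(self, rng):
        anc = random_protein(rng, 120)
        domain = random_protein(rng, 80)
        rep = transcript(
            anc + domain,
            [(0, 60), (60, 120), (120, 160), (160, 200)],
            (0, 1, 2),
        )
        call = classify_gain_structure(rep, [anc], (120, 200))
        assert call.position == CARBOXY
        assert call.exon_category == MULTIPLE_NEW
        assert call.n_new_exons == 2

    def test_middle_single_novel_exon(self, rng):
        anc = random_protein(rng, 150)
        domain = random_protein(rng, 60)
        rep = transcript(
            anc[:50] + domain + anc[50:],
            [(0, 50), (50, 110), (110, 160), (160, 210)],
            (0, 1, 1),
        )
        call = classify_gain_structure(rep, [anc], (50, 110))
        assert call.position == MIDDLE
        assert call.exon_category == SINGLE_NEW
        assert call.flanking_phases == (0, 1)
        assert call.symmetric_phase_flag is False

    def test_extension_only_when_exon_extended(self, rng):
        anc = random_protein(rng, 116)
        domain = random_protein(rng, 60)
        rep = transcript(
            anc + domain,
            [(0, 40), (40, 80), (80, 176)],
            (0, 2),
        )
        call = classify_gain_structure(rep, [anc], (116, 176))
        assert call.position == CARBOXY
        assert call.exon_category == EXTENSION_ONLY
        assert call.n_new_exons == 0

    def test_terminal_when_intervening_exons_are_novel(self, rng):
        """Domain not in the last exon, but every exon between it and the
        carboxy terminus is novel -> still a terminal gain."""
        anc = random_protein(rng, 100)
        block = random_protein(rng, 90)
        # exons: anc | anc | domain exon | novel trailing exon
        rep = transcript(
            anc + block,
            [(0, 50), (50, 100), (100, 160), (160, 190)],
            (0, 1, 0),
        )
        call = classify_gain_structure(rep, [anc], (100, 160))
        assert call.position == CARBOXY
        assert call.n_new_exons == 2

    def test_no_homologs_gives_ambiguous(self, rng):
        rep = transcript(
            random_protein(rng, 100), [(0, 50), (50, 100)], (0,)
        )
        call = classify_gain_structure(rep, [], (50, 100))
        assert call.position == AMBIGUOUS
        assert call.exon_category == AMBIGUOUS

    def test_invariant_category_constraints(self):
        with pytest.raises(ValueError):
            StructureCall(MIDDLE, EXTENSION_ONLY, n_new_exons=1)
        with pytest.raises(ValueError):
            StructureCall(MIDDLE, MULTIPLE_NEW, n_new_exons=1)

    def test_homolog_order_and_duplicates_do_not_matter(self, rng):
        anc = random_protein(rng, 120)
        other = random_protein(rng, 110)
        domain = random_protein(rng, 60)
        rep = transcript(
            anc[:60] + domain + anc[60:],
            [(0, 60), (60, 120), (120, 180)],
            (0, 0),
        )
        span = (60, 120)
        calls = [
            classify_gain_structure(rep, homs, span)
            for homs in ([anc, other], [other, anc], [anc, anc, other])
        ]
        assert all(c == calls[0] for c in calls)
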