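"""Donor-gene search and mechanism classification of domain gains.

A gained domain usually came from somewhere: if a significant, non-paralog
copy of the domain sequence exists elsewhere in the proteome, that gene is a
candidate *donor*.  The structural signature of the gain, combined with the
donor evidence, points at the molecular mechanism:

* terminal gain coded by >= 2 novel exons -> joining of exons from an
  adjacent gene (gene fusion);
* domain within a single novel exon with an identifiable donor -> candidate
  retroposition (reinserted processed mRNA copies are intronless);
* middle gain of novel exon(s) flanked by introns of equal phases ->
  insertion into an ancestral intron;
* extension of an ancestral exon with no new exons -> candidate exonization
  of previously non-coding sequence.

The labels are evidential hypotheses, not proofs; each call records the
rule that fired.  Retroposition can never be assigned to a domain coded by
multiple exons — intron presence rules it out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import ScoringConfig, ThresholdConfig
from .gain_inference import GainEvent
from .io_model import SegDupPair
from .refinement import AlignmentResult, pairwise_align
from .structure_classification import (
    AMBIGUOUS,
    AMINO,
    CARBOXY,
    EXTENSION_ONLY,
    MIDDLE,
    SINGLE_NEW,
    StructureCall,
)

RETROPOSITION = "retroposition_candidate"
ADJACENT_JOINING = "adjacent_gene_joining"
INTRONIC_INSERTION = "intronic_insertion"
EXONIZATION = "exonization_candidate"
UNCLASSIFIED = "unclassified"

MECHANISMS = (
    RETROPOSITION,
    ADJACENT_JOINING,
    INTRONIC_INSERTION,
    EXONIZATION,
    UNCLASSIFIED,
)


@dataclass
class ProteomeEntry:
    """One searchable proteome protein with genomic metadata."""

    protein_id: str
    gene_id: str
    sequence: str
    chromosome: str | None = None
    genomic_span: tuple[int, int] | None = None


@dataclass
class DonorCall:
    """Best non-paralog donor candidate for one gained domain, if any."""

    donor_protein_id: str | None = None
    donor_gene_id: str | None = None
    alignment: AlignmentResult | None = None
    same_chromosome: bool | None = None
    via_segdup: bool | None = None

    @property
    def found(self) -> bool:
        return self.donor_protein_id is not None


@dataclass
class MechanismCall:
    label: str
    rule: str = ""
    notes: str = ""


def _seed_index(sequence: str, k: int) -> set[str]:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def donor_significant(evalue: float, domain_coverage: float,
                      cfg: ThresholdConfig) -> bool:
    """Donor-hit rule: E-value strictly below the cutoff AND at least 60%
    of the gained-domain sequence aligned."""
    return evalue < cfg.donor_evalue and domain_coverage >= cfg.donor_coverage


def find_donor(
    domain_sequence: str,
    proteome: Sequence[ProteomeEntry],
    paralog_genes: Iterable[str],
    recipient_chromosome: str | None = None,
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
    seed_k: int | None = 4,
) -> DonorCall:
    """Search a proteome for the origin of a gained domain.

    The best-scoring hit outside the recipient's paralog set qualifies as a
    donor iff its E-value is below ``cfg.donor_evalue`` and at least
    ``cfg.donor_coverage`` of the domain sequence is aligned.  Ties break by
    (lower E-value, lexicographic protein id).  ``seed_k``-mer prefiltering
    skips targets sharing no exact word with the query (blast-like seeding);
    the E-value search space is still the total residues in the proteome.
    """
    if not proteome:
        raise ValueError("empty proteome")
    cfg = cfg or ThresholdConfig()
    paralogs = set(paralog_genes)
    search_space = sum(len(p.sequence) for p in proteome)
    seeds = _seed_index(domain_sequence, seed_k) if seed_k else None

    best: tuple[float, str, ProteomeEntry, AlignmentResult] | None = None
    for entry in proteome:
        if entry.gene_id in paralogs:
            continue
        if not entry.sequence:
            continue
        if seeds is not None and not any(
            entry.sequence[i : i + seed_k] in seeds
            for i in range(len(entry.sequence) - seed_k + 1)
        ):
            continue
        res = pairwise_align(
            domain_sequence, entry.sequence,
            scoring=scoring, search_space=search_space,
        )
        if not donor_significant(res.significance, res.query_coverage, cfg):
            continue
        key = (res.significance, entry.protein_id)
        if best is None or key < (best[0], best[1]):
            best = (res.significance, entry.protein_id, entry, res)

    if best is None:
        return DonorCall()
    _, _, entry, res = best
    same_chrom = None
    if recipient_chromosome is not None and entry.chromosome is not None:
        same_chrom = entry.chromosome == recipient_chromosome
    return DonorCall(
        donor_protein_id=entry.protein_id,
        donor_gene_id=entry.gene_id,
        alignment=res,
        same_chromosome=same_chrom,
    )


def classify_mechanism(
    structure: StructureCall, donor: DonorCall
) -> MechanismCall:
    """Rule-ordered mechanism call from structural + donor evidence.

    Pure function of its inputs.  Precedence (adjacent joining before
    retroposition) reflects that several single-exon candidates are better
    explained by exon joining from adjacent genes.
    """
    if structure.position == AMBIGUOUS or structure.exon_category == AMBIGUOUS:
        return MechanismCall(UNCLASSIFIED, rule="ambiguous_structure")
    terminal = structure.position in (AMINO, CARBOXY)
    if terminal and structure.n_new_exons >= 2:
        return MechanismCall(
            ADJACENT_JOINING,
            rule="terminal_multiple_new_exons",
            notes=f"{structure.n_new_exons} novel terminal exons",
        )
    if structure.exon_category == SINGLE_NEW and donor.found:
        return MechanismCall(
            RETROPOSITION,
            rule="single_exon_with_donor",
            notes=f"donor={donor.donor_gene_id}",
        )
    if (
        structure.position == MIDDLE
        and structure.n_new_exons >= 1
        and structure.symmetric_phase_flag
    ):
        return MechanismCall(
            INTRONIC_INSERTION,
            rule="middle_novel_symmetric_phases",
            notes=f"phases={structure.flanking_phases}",
        )
    if structure.exon_category == EXTENSION_ONLY:
        return MechanismCall(EXONIZATION, rule="extension_only")
    return MechanismCall(UNCLASSIFIED, rule="no_rule_fired")


@dataclass
class ClassifiedEvent:
    """A gain event with structure, donor, and mechanism attached."""

    event: GainEvent
    structure: StructureCall
    donor: DonorCall
    mechanism: MechanismCall
    extras: dict = field(default_factory=dict)


def donor_chromosome_by_age(
    classified: Sequence[ClassifiedEvent],
    age_groups: Sequence[str],
) -> dict[str, tuple[int, int]]:
    """Per age group: (events with a same-chromosome donor, total events).

    Events without a donor, or without chromosome metadata, count in the
    denominator only.  Groups with no events report (0, 0).
    """
    table = {g: [0, 0] for g in age_groups}
    for ce in classified:
        group = ce.event.age_group
        if group not in table:
            table[group] = [0, 0]
        table[group][1] += 1
        if ce.donor.found and ce.donor.same_chromosome:
            table[group][0] += 1
    return {g: (n, total) for g, (n, total) in table.items()}


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]  # half-open, >= 1 base


def segdup_support(
    recipient: tuple[str, tuple[int, int]],
    donor: tuple[str, tuple[int, int]] | None,
    donor_paralogs: Sequence[tuple[str, tuple[int, int]]],
    segdup_pairs: Sequence[SegDupPair],
) -> bool | None:
    """True iff one side of a segmental-duplication pair overlaps the
    recipient gene and the mate overlaps the donor gene or one of its
    paralogs.  ``None`` (undefined) when coordinates are missing.
    """
    if recipient[1] is None or donor is None or donor[1] is None:
        return None
    donor_side = [donor] + [p for p in donor_paralogs if p[1] is not None]

    def side_hits(chrom: str, span: tuple[int, int],
                  gene: tuple[str, tuple[int, int]]) -> bool:
        return chrom == gene[0] and _overlaps(span, gene[1])

    for pair in segdup_pairs:
        ends = (
            (pair.chrom1, (pair.start1, pair.end1)),
            (pair.chrom2, (pair.start2, pair.end2)),
        )
        for first, second in (ends, ends[::-1]):
            if side_hits(first[0], first[1], recipient) and any(
                side_hits(second[0], second[1], g) for g in donor_side
            ):
                return True
    return False


def event_mechanism_counts(
    classified: Sequence[ClassifiedEvent],
) -> Mapping[str, int]:
    counts = {m: 0 for m in MECHANISMS}
    for ce in classified:
        counts[ce.mechanism.label] += 1
    return counts
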