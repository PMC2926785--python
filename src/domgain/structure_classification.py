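"""Coding-structure classification of gained domains.

For each gain event the representative transcript's exon model is compared
against the family members that lack the gained domain ("homologs").  The
representative is aligned to each homolog full-length with free end gaps —
the pairwise analogue of reading a family alignment — and per-residue
aligned/identical profiles are projected onto the exon model.  The
classification answers three questions:

* position — is the domain at the amino terminus, the carboxy terminus, or
  in the middle of the protein?
* exon category — is the domain coded by multiple new exons, a single new
  exon, an extended ancestral exon plus new exons, or an extended ancestral
  exon alone?
* phase symmetry — for middle gains, do the introns flanking the novel exon
  block have equal phases (the classic exon-shuffling signature: a clean
  insertion into an ancestral intron preserves reading frame only when the
  flanking intron phases match)?

Exon novelty rules: an exon is novel when >= 85% of
its residues are unaligned against every homolog, or when its best identity
to any homolog (identical residues over exon length) is < 10% — < 40% for
exons of <= 20 residues.  An exon partially overlapped by the domain is an
*extension* of an ancestral exon when the first/last third of its sequence
outside the domain is >= 7 residues long and >= 30% identical to some
homolog.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .config import ScoringConfig, ThresholdConfig
from .io_model import GeneFamily, Transcript
from .refinement import residue_profile

AMINO = "amino_terminal"
CARBOXY = "carboxy_terminal"
MIDDLE = "middle"
AMBIGUOUS = "ambiguous"

MULTIPLE_NEW = "multiple_new_exons"
SINGLE_NEW = "single_new_exon"
EXTENSION_PLUS = "extension_plus_new_exons"
EXTENSION_ONLY = "extension_only"

POSITIONS = (AMINO, CARBOXY, MIDDLE, AMBIGUOUS)
CATEGORIES = (MULTIPLE_NEW, SINGLE_NEW, EXTENSION_PLUS, EXTENSION_ONLY, AMBIGUOUS)


@dataclass
class ExonHomology:
    """Per-exon similarity evidence against the domain-lacking homologs."""

    exon_index: int
    start: int
    end: int
    unaligned_fraction: float
    max_identity: float
    novel: bool
    indeterminate: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StructureCall:
    """Structural classification of one gain event."""

    position: str
    exon_category: str
    n_new_exons: int
    flanking_phases: tuple[int, int] | None = None
    symmetric_phase_flag: bool | None = None
    extension_flags: tuple[bool, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        if self.exon_category == EXTENSION_ONLY and self.n_new_exons != 0:
            raise ValueError("extension_only implies zero new exons")
        if self.exon_category == MULTIPLE_NEW and self.n_new_exons < 2:
            raise ValueError("multiple_new_exons implies >= 2 new exons")


class HomologProfiles:
    """Aligned/identical per-residue profiles of one representative protein
    against each homolog; shared by the novelty and extension tests so the
    alignments are computed once per event."""

    def __init__(
        self,
        representative: Transcript,
        homologs: Sequence[str],
        scoring: ScoringConfig | None = None,
    ) -> None:
        self.length = len(representative.protein_sequence)
        self.aligned: list[list[bool]] = []
        self.identical: list[list[bool]] = []
        for hom in homologs:
            if not hom:
                continue
            a, i = residue_profile(
                representative.protein_sequence, hom, scoring
            )
            self.aligned.append(a)
            self.identical.append(i)

    @property
    def n_homologs(self) -> int:
        return len(self.aligned)

    def unaligned_fraction(self, start: int, end: int) -> float:
        """Fraction of region residues unaligned against every homolog."""
        if end <= start:
            return 0.0
        unaligned = 0
        for pos in range(start, end):
            if not any(a[pos] for a in self.aligned):
                unaligned += 1
        return unaligned / (end - start)

    def max_identity(self, start: int, end: int) -> float:
        """Best identical-residue fraction over the region, over homologs."""
        if end <= start or not self.identical:
            return 0.0
        length = end - start
        return max(
            sum(ident[start:end]) / length for ident in self.identical
        )


def _is_novel(length: int, unaligned: float, max_identity: float,
              cfg: ThresholdConfig) -> bool:
    identity_cutoff = (
        cfg.short_exon_max_identity
        if length <= cfg.short_exon_len
        else cfg.novel_exon_max_identity
    )
    return unaligned >= cfg.novel_exon_novel_fraction or max_identity < identity_cutoff


def per_exon_homology(
    representative: Transcript,
    homologs: Sequence[str],
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
    profiles: HomologProfiles | None = None,
) -> list[ExonHomology]:
    """Novelty evidence for every exon of the representative transcript.

    With no homologs available every exon is flagged indeterminate and the
    event is classified ambiguous downstream.
    """
    cfg = cfg or ThresholdConfig()
    if representative.exon_model is None:
        raise ValueError(
            f"{representative.transcript_id} has no exon model attached"
        )
    if profiles is None:
        profiles = HomologProfiles(representative, homologs, scoring)
    table: list[ExonHomology] = []
    for i, (start, end) in enumerate(representative.exon_model.exons):
        if profiles.n_homologs == 0:
            table.append(
                ExonHomology(i, start, end, 1.0, 0.0, novel=False,
                             indeterminate=True)
            )
            continue
        unaligned = profiles.unaligned_fraction(start, end)
        identity = profiles.max_identity(start, end)
        table.append(
            ExonHomology(
                i, start, end, unaligned, identity,
                novel=_is_novel(end - start, unaligned, identity, cfg),
            )
        )
    return table


def detect_exon_extension(
    representative: Transcript,
    homologs: Sequence[str],
    gained_span: tuple[int, int],
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
    profiles: HomologProfiles | None = None,
) -> dict[int, bool]:
    """Extension flags for exons partially overlapped by the gained domain.

    For each such exon, the first (upstream side) or last (downstream side)
    third of the exon sequence *outside* the domain — rounded down, never
    shorter than the 7-residue minimum — is tested; the flag is true iff
    that boundary region is >= 7 residues long and shares >= 30% identical
    residues with some homolog.  Shorter regions are not tested (flag
    false).
    """
    cfg = cfg or ThresholdConfig()
    if representative.exon_model is None:
        raise ValueError("representative lacks an exon model")
    if profiles is None:
        profiles = HomologProfiles(representative, homologs, scoring)
    d_start, d_end = gained_span
    flags: dict[int, bool] = {}
    for i, (start, end) in enumerate(representative.exon_model.exons):
        if end <= d_start or start >= d_end:
            continue  # exon does not overlap the domain
        if start >= d_start and end <= d_end:
            continue  # exon fully inside the domain: nothing outside to test
        regions: list[tuple[int, int]] = []
        if start < d_start:  # outside residues upstream of the domain
            n_outside = d_start - start
            third = max(n_outside // 3, cfg.boundary_min_len)
            regions.append((start, min(start + third, d_start)))
        if end > d_end:  # outside residues downstream of the domain
            n_outside = end - d_end
            third = max(n_outside // 3, cfg.boundary_min_len)
            regions.append((max(end - third, d_end), end))
        flag = False
        for r_start, r_end in regions:
            if r_end - r_start < cfg.boundary_min_len or profiles.n_homologs == 0:
                continue
            if profiles.max_identity(r_start, r_end) >= cfg.boundary_identity:
                flag = True
        flags[i] = flag
    return flags


def _novel_block(
    novel: Sequence[bool], domain_exons: Sequence[int]
) -> tuple[int, int] | None:
    """Maximal run of contiguous novel exons containing the domain's novel
    exons; None when the domain covers no novel exon."""
    seed = [i for i in domain_exons if novel[i]]
    if not seed:
        return None
    lo, hi = min(seed), max(seed)
    while lo > 0 and novel[lo - 1]:
        lo -= 1
    while hi < len(novel) - 1 and novel[hi + 1]:
        hi += 1
    return lo, hi


def check_symmetric_phases(
    representative: Transcript, block: tuple[int, int] | None
) -> tuple[tuple[int, int] | None, bool | None]:
    """Flanking intron phases of a middle novel-exon block and their equality.

    Returns ``(phases, flag)``; both ``None`` when a flanking intron is
    missing (terminal block) — recorded as not-applicable, not an error.
    """
    if block is None or representative.exon_model is None:
        return None, None
    lo, hi = block
    model = representative.exon_model
    if lo == 0 or hi >= model.n_exons - 1:
        return None, None
    upstream = model.phases[lo - 1]
    downstream = model.phases[hi]
    return (upstream, downstream), upstream == downstream


def classify_gain_structure(
    representative: Transcript,
    homologs: Sequence[str],
    gained_span: tuple[int, int],
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
) -> StructureCall:
    """Full structural call for one gain event.

    Position: a domain lying in the first (last) coding exon is an amino-
    (carboxy-)terminal gain; a domain not in a terminal exon is still
    terminal when every exon between it and the terminus is novel (gained
    together with the domain); everything else is middle.  The exon category
    follows from the count of novel exons in the domain's novel block and
    the extension flags of partially-overlapped boundary exons.
    """
    cfg = cfg or ThresholdConfig()
    model = representative.exon_model
    if model is None:
        raise ValueError("representative lacks an exon model")
    profiles = HomologProfiles(representative, homologs, scoring)
    exon_table = per_exon_homology(
        representative, homologs, cfg, scoring, profiles=profiles
    )
    if any(e.indeterminate for e in exon_table):
        return StructureCall(
            position=AMBIGUOUS,
            exon_category=AMBIGUOUS,
            n_new_exons=0,
            notes="no homologs available",
        )

    d_start, d_end = gained_span
    domain_exons = [
        i for i, (s, e) in enumerate(model.exons)
        if not (e <= d_start or s >= d_end)
    ]
    if not domain_exons:
        return StructureCall(
            position=AMBIGUOUS, exon_category=AMBIGUOUS, n_new_exons=0,
            notes="gained span overlaps no exon",
        )

    novel = [e.novel for e in exon_table]
    ext_flags = detect_exon_extension(
        representative, homologs, gained_span, cfg, scoring, profiles=profiles
    )
    any_extension = any(ext_flags.values())
    block = _novel_block(novel, domain_exons)
    n_new = 0 if block is None else block[1] - block[0] + 1

    # position ---------------------------------------------------------
    # the novel block is a maximal run, so "every exon between the domain
    # and a terminus is novel" is equivalent to the block reaching that
    # terminus; the explicit first/last-exon rule takes precedence
    n_exons = model.n_exons
    first_exon, last_exon = domain_exons[0], domain_exons[-1]
    if first_exon == 0:
        position = AMINO
    elif last_exon == n_exons - 1:
        position = CARBOXY
    elif block is not None and block[0] == 0:
        position = AMINO
    elif block is not None and block[1] == n_exons - 1:
        position = CARBOXY
    else:
        position = MIDDLE

    # category ---------------------------------------------------------
    if any_extension and n_new >= 1:
        category = EXTENSION_PLUS
    elif any_extension:
        category = EXTENSION_ONLY
    elif n_new >= 2:
        category = MULTIPLE_NEW
    elif n_new == 1:
        category = SINGLE_NEW
    else:
        # zero novel exons and no extension: conflicting evidence
        return StructureCall(
            position=AMBIGUOUS,
            exon_category=AMBIGUOUS,
            n_new_exons=0,
            notes="no novel exons and no extension",
        )

    phases, symmetric = (None, None)
    if position == MIDDLE:
        phases, symmetric = check_symmetric_phases(representative, block)

    return StructureCall(
        position=position,
        exon_category=category,
        n_new_exons=n_new,
        flanking_phases=phases,
        symmetric_phase_flag=symmetric,
        extension_flags=tuple(ext_flags.values()),
    )


def gained_domain_span(
    family: GeneFamily, transcript_id: str, character_ids: Sequence[str]
) -> tuple[int, int]:
    """Union span of the gained character's hit envelopes on a transcript."""
    spans = [
        (h.start, h.end)
        for h in family.hits
        if h.sequence_id == transcript_id and h.character_id in character_ids
    ]
    if not spans:
        raise ValueError(f"no hits for {character_ids} on {transcript_id}")
    return min(s for s, _ in spans), max(e for _, e in spans)


def homolog_sequences(
    family: GeneFamily, character_ids: Sequence[str]
) -> list[str]:
    """Tree-transcript protein sequences of family genes lacking the
    gained character (order-stable, deduplicated)."""
    with_char = {
        h.sequence_id for h in family.hits if h.character_id in character_ids
    }
    seqs: list[str] = []
    seen: set[str] = set()
    for gene in family.tree.leaf_names():
        t = family.tree_transcript_of(gene)
        if t.transcript_id in with_char:
            continue
        if t.protein_sequence not in seen:
            seen.add(t.protein_sequence)
            seqs.append(t.protein_sequence)
    return seqs
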