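"""Pairwise protein alignment and domain-annotation refinement.

The refinement stage repairs two failure modes of HMM-based domain
annotation before any gain/loss inference is attempted:

* spurious fragmentary hits (singleton in the family, weak E-value, low
  model coverage) are removed — these would otherwise look like gains;
* genuinely present domains that the HMM missed are rescued by aligning the
  un-annotated sequence against the family's instances of the domain —
  these would otherwise look like losses.

Alignment is affine-gap Smith–Waterman (BLOSUM62, open 11 / extend 1) via
Biopython's :class:`PairwiseAligner`; significance is a Karlin–Altschul
E-value with published gapped BLOSUM62 constants.  The constants and the
search space are explicit parameters so the significance regime is fully
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .config import ScoringConfig, ThresholdConfig
from .io_model import DomainHit, GeneFamily

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class AlignmentResult:
    """Summary of one pairwise local alignment.

    ``identity_fraction`` is identical residues over aligned columns
    (gap columns excluded); ``identical_residues`` is the raw identical
    count, from which per-region identities (relative to a region length)
    are derived by callers.  ``query_coverage`` is aligned query residues
    over the full query length.  ``significance`` is the Karlin–Altschul
    E-value for the configured search space.
    """

    score: float
    aligned_length: int
    identical_residues: int
    query_coverage: float
    significance: float
    query_aligned_columns: tuple[tuple[int, int], ...] = ()
    target_aligned_columns: tuple[tuple[int, int], ...] = ()

    @property
    def identity_fraction(self) -> float:
        if self.aligned_length == 0:
            return 0.0
        return self.identical_residues / self.aligned_length


def _make_aligner(scoring: ScoringConfig, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global" if mode == "overlap" else mode
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix_name)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    if mode == "overlap":
        aligner.end_gap_score = 0.0
    return aligner


def karlin_altschul_evalue(
    score: float, query_len: int, search_space: int, scoring: ScoringConfig
) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    return (
        scoring.karlin_k
        * query_len
        * search_space
        * math.exp(-scoring.karlin_lambda * score)
    )


def pairwise_align(
    query: str,
    target: str,
    scoring: ScoringConfig | None = None,
    search_space: int | None = None,
    mode: str = "local",
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    Deterministic: when several optimal paths exist the aligner's first
    enumerated path is used.  ``search_space`` defaults to the target
    length; operations scanning many targets pass the total residues
    scanned so that E-values reflect the whole search.
    """
    scoring = scoring or ScoringConfig()
    for name, seq in (("query", query), ("target", target)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"{name} contains invalid residues: {sorted(bad)}")

    aligner = _make_aligner(scoring, mode)
    alignments = aligner.align(query, target)
    if len(alignments) == 0 or alignments.score <= 0:
        return AlignmentResult(
            score=0.0,
            aligned_length=0,
            identical_residues=0,
            query_coverage=0.0,
            significance=math.inf,
        )
    aln = alignments[0]
    counts = aln.counts()
    aligned_length = counts.identities + counts.mismatches
    q_blocks, t_blocks = aln.aligned
    q_cols = tuple((int(a), int(b)) for a, b in q_blocks)
    t_cols = tuple((int(a), int(b)) for a, b in t_blocks)
    aligned_query = sum(b - a for a, b in q_cols)
    n = search_space if search_space is not None else len(target)
    return AlignmentResult(
        score=float(aln.score),
        aligned_length=aligned_length,
        identical_residues=counts.identities,
        query_coverage=aligned_query / len(query),
        significance=karlin_altschul_evalue(aln.score, len(query), n, scoring),
        query_aligned_columns=q_cols,
        target_aligned_columns=t_cols,
    )


def residue_profile(
    query: str, target: str, scoring: ScoringConfig | None = None
) -> tuple[list[bool], list[bool]]:
    """Per-residue alignment profile of ``query`` against ``target``.

    The two sequences are aligned globally with free end gaps (overlap
    mode) — the pairwise analogue of reading a family alignment column-wise.
    Returns two boolean lists over query positions: ``aligned[i]`` (the
    residue sits in a non-gap column) and ``identical[i]`` (it is aligned to
    an identical residue).  Residues of an inserted block absent from the
    target fall in gap columns, which is what the exon-novelty and
    similarity-exclusion identity rules count.
    """
    scoring = scoring or ScoringConfig()
    aligner = _make_aligner(scoring, "overlap")
    aln = aligner.align(query, target)[0]
    aligned = [False] * len(query)
    identical = [False] * len(query)
    q_blocks, t_blocks = aln.aligned
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for offset in range(qe - qs):
            qi = qs + offset
            aligned[qi] = True
            if query[qi] == target[ts + offset]:
                identical[qi] = True
    return aligned, identical


# ---------------------------------------------------------------------------
# refinement operations
# ---------------------------------------------------------------------------


def apply_clan_mapping(
    hits: Sequence[DomainHit], clan_map: Mapping[str, str]
) -> list[DomainHit]:
    """Attach clan ids so related domain families share one character.

    Hits whose ``domain_id`` is absent from the (possibly partial) map keep
    their domain id as character.
    """
    return [
        replace(h, clan_id=clan_map.get(h.domain_id, h.clan_id)) for h in hits
    ]


def is_fragmentary(
    hit: DomainHit, n_sequences_with_character: int, cfg: ThresholdConfig
) -> bool:
    """Fragment rule: singleton in the family AND E-value above the cutoff
    AND at most 30% of the domain model covered.  All three must hold."""
    return (
        n_sequences_with_character == 1
        and hit.e_value > cfg.fragment_evalue
        and hit.model_coverage <= cfg.fragment_model_coverage
    )


def remove_fragmentary_hits(
    family: GeneFamily, cfg: ThresholdConfig | None = None
) -> GeneFamily:
    """Drop likely false-positive fragmentary hits from a family."""
    cfg = cfg or ThresholdConfig()
    seqs_with: dict[str, set[str]] = {}
    for h in family.hits:
        seqs_with.setdefault(h.character_id, set()).add(h.sequence_id)
    kept = [
        h
        for h in family.hits
        if not is_fragmentary(h, len(seqs_with[h.character_id]), cfg)
    ]
    return GeneFamily(
        family_id=family.family_id,
        tree=family.tree,
        transcripts=family.transcripts,
        hits=kept,
        tree_transcript=dict(family.tree_transcript),
    )


def passes_rescue(evalue: float, fraction_present: float,
                  cfg: ThresholdConfig) -> bool:
    """True iff any rescue tier admits the alignment."""
    return any(t.passes(evalue, fraction_present) for t in cfg.rescue_tiers)


def rescue_missing_domains(
    family: GeneFamily,
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
) -> GeneFamily:
    """Add domains the HMM scan missed on some family members.

    For every (sequence, character) pair where the sequence lacks a
    character that at least one other family member carries, the sequence
    is aligned against each family instance of that domain.  A hit is added
    when any alignment passes a rescue tier; the instance with the lowest
    E-value wins and the added hit is flagged ``provenance="rescued"``.
    Idempotent: rescued hits satisfy the presence check on a second pass.
    """
    cfg = cfg or ThresholdConfig()
    scoring = scoring or ScoringConfig()

    instances: dict[str, list[tuple[str, int, int]]] = {}
    for h in family.hits:
        instances.setdefault(h.character_id, []).append(
            (h.sequence_id, h.start, h.end)
        )
    present: dict[str, set[str]] = {
        char: {sid for sid, _, _ in insts} for char, insts in instances.items()
    }

    new_hits: list[DomainHit] = []
    for t in family.all_transcripts():
        for char, insts in sorted(instances.items()):
            if t.transcript_id in present[char]:
                continue
            best: tuple[float, AlignmentResult, str, int, int] | None = None
            search_space = sum(e - s for _, s, e in insts)
            for sid, s, e in insts:
                domain_seq = family.transcript(sid).protein_sequence[s:e]
                if not domain_seq:
                    continue
                res = pairwise_align(
                    domain_seq,
                    t.protein_sequence,
                    scoring=scoring,
                    search_space=search_space,
                )
                if passes_rescue(res.significance, res.query_coverage, cfg):
                    key = res.significance
                    if best is None or key < best[0]:
                        best = (key, res, sid, s, e)
            if best is not None:
                _, res, sid, s, e = best
                t_cols = res.target_aligned_columns
                start = t_cols[0][0] if t_cols else 0
                end = t_cols[-1][1] if t_cols else len(t.protein_sequence)
                template = next(
                    h for h in family.hits
                    if h.sequence_id == sid and h.character_id == char
                )
                new_hits.append(
                    DomainHit(
                        sequence_id=t.transcript_id,
                        domain_id=template.domain_id,
                        start=start,
                        end=end,
                        e_value=max(res.significance, 1e-300),
                        model_coverage=res.query_coverage,
                        clan_id=template.clan_id,
                        provenance="rescued",
                    )
                )
    if not new_hits:
        return family
    return GeneFamily(
        family_id=family.family_id,
        tree=family.tree,
        transcripts=family.transcripts,
        hits=list(family.hits) + new_hits,
        tree_transcript=dict(family.tree_transcript),
    )
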