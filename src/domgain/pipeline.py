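"""End-to-end orchestration: refined annotations -> gain events ->
structure, donor and mechanism calls -> summary statistics.

``analyze_dataset`` is the programmatic entry point; ``load_dataset`` reads
a directory in the on-disk layout produced by
:meth:`domgain.simulate.SimulatedDataset.write` (the same layout any real
dataset can be converted to).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import (
    DEFAULT_CLADE_MAP,
    QUALITY_SPECIES,
    ScoringConfig,
    ThresholdConfig,
)
from .gain_inference import (
    FamilyGainResult,
    GainEvent,
    infer_family_gains,
    merge_stage_counts,
)
from .io_model import (
    DisorderTrack,
    GeneFamily,
    SegDupPair,
    Transcript,
    parse_gene_tree,
    read_clan_map,
    read_disorder_tracks,
    read_domain_hits,
    read_fasta,
    read_gene_structure,
    read_segdup_pairs,
)
from .mechanism_donor import (
    ClassifiedEvent,
    DonorCall,
    ProteomeEntry,
    classify_mechanism,
    find_donor,
    segdup_support,
)
from .refinement import apply_clan_mapping, remove_fragmentary_hits, \
    rescue_missing_domains
from .structure_classification import (
    classify_gain_structure,
    gained_domain_span,
    homolog_sequences,
)


@dataclass
class AnalysisResult:
    classified: list[ClassifiedEvent]
    funnel: dict[str, int]
    families: dict[str, GeneFamily]  # refined families by id
    per_family: list[FamilyGainResult] = field(default_factory=list)


def refine_family(
    family: GeneFamily,
    clan_map: Mapping[str, str] | None = None,
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
    rescue: bool = True,
) -> GeneFamily:
    """Clan-collapse, fragment-filter and rescue one family's annotations."""
    cfg = cfg or ThresholdConfig()
    hits = apply_clan_mapping(family.hits, clan_map or {})
    fam = GeneFamily(
        family_id=family.family_id,
        tree=family.tree,
        transcripts=family.transcripts,
        hits=hits,
        tree_transcript=dict(family.tree_transcript),
    )
    fam = remove_fragmentary_hits(fam, cfg)
    if rescue:
        fam = rescue_missing_domains(fam, cfg, scoring)
    return fam


def classify_event(
    event: GainEvent,
    family: GeneFamily,
    proteome: Sequence[ProteomeEntry],
    segdups: Sequence[SegDupPair] = (),
    extra_paralogs: Iterable[str] = (),
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
) -> ClassifiedEvent:
    """Structure, donor and mechanism calls for one gain event."""
    cfg = cfg or ThresholdConfig()
    rep = family.transcript(event.representative_transcript)
    span = gained_domain_span(family, rep.transcript_id, event.character_ids)
    homologs = homolog_sequences(family, event.character_ids)
    structure = classify_gain_structure(rep, homologs, span, cfg, scoring)

    donor = DonorCall()
    if proteome:
        domain_seq = rep.protein_sequence[span[0]:span[1]]
        paralogs = set(family.transcripts) | set(extra_paralogs)
        donor = find_donor(
            domain_seq,
            proteome,
            paralogs,
            recipient_chromosome=rep.chromosome,
            cfg=cfg,
            scoring=scoring,
        )
    if donor.found and segdups:
        donor_entry = next(
            p for p in proteome if p.protein_id == donor.donor_protein_id
        )
        if rep.genomic_span is not None and donor_entry.genomic_span is not None:
            donor.via_segdup = segdup_support(
                (rep.chromosome, rep.genomic_span),
                (donor_entry.chromosome, donor_entry.genomic_span),
                [],
                segdups,
            )
    mechanism = classify_mechanism(structure, donor)
    return ClassifiedEvent(
        event=event, structure=structure, donor=donor, mechanism=mechanism
    )


def analyze_dataset(
    families: Sequence[GeneFamily],
    proteome: Sequence[ProteomeEntry] = (),
    clan_map: Mapping[str, str] | None = None,
    segdups: Sequence[SegDupPair] = (),
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
    quality_species: Iterable[str] = QUALITY_SPECIES,
    preferred_species: str = "human",
    clade_map: Sequence[tuple[str, frozenset[str]]] = DEFAULT_CLADE_MAP,
    blacklist: Iterable[tuple[str, str]] = (),
    rescue: bool = True,
) -> AnalysisResult:
    """Run the full pipeline over a set of families."""
    cfg = cfg or ThresholdConfig()
    refined: dict[str, GeneFamily] = {}
    per_family: list[FamilyGainResult] = []
    classified: list[ClassifiedEvent] = []
    for family in families:
        fam = refine_family(family, clan_map, cfg, scoring, rescue=rescue)
        refined[fam.family_id] = fam
        result = infer_family_gains(
            fam, cfg, scoring, quality_species, preferred_species,
            clade_map, blacklist,
        )
        per_family.append(result)
        for event in result.events:
            classified.append(
                classify_event(
                    event, fam, proteome, segdups, cfg=cfg, scoring=scoring
                )
            )
    return AnalysisResult(
        classified=classified,
        funnel=merge_stage_counts(per_family),
        families=refined,
        per_family=per_family,
    )


# ---------------------------------------------------------------------------
# on-disk dataset loading
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    families: list[GeneFamily]
    proteome: list[ProteomeEntry]
    tracks: dict[str, DisorderTrack]
    segdups: list[SegDupPair]
    clan_map: dict[str, str]


def load_dataset(data_dir: str) -> Dataset:
    """Load a dataset directory (trees, structures, hits, proteome FASTA,
    transcript metadata, clan map, disorder tracks, BEDPE)."""
    path = lambda name: os.path.join(data_dir, name)  # noqa: E731

    structures = read_gene_structure(path("structures.tsv"))
    sequences = read_fasta(path("proteome.fasta"))
    all_hits = read_domain_hits(path("hits.tsv"))
    clan_map = (
        read_clan_map(path("clan_map.tsv"))
        if os.path.exists(path("clan_map.tsv")) else {}
    )
    tracks = (
        read_disorder_tracks(path("disorder.tsv"))
        if os.path.exists(path("disorder.tsv")) else {}
    )
    segdups = (
        read_segdup_pairs(path("segdups.bedpe"))
        if os.path.exists(path("segdups.bedpe")) else []
    )

    # transcript metadata
    meta: dict[str, dict] = {}
    with open(path("transcripts.tsv")) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            tid, gene, fam, species, chrom, start, end, is_tree = (
                line.rstrip("\n").split("\t")
            )
            meta[tid] = {
                "gene": gene, "family": fam, "species": species,
                "chromosome": chrom, "span": (int(start), int(end)),
                "is_tree": is_tree == "1",
            }

    hits_by_tid: dict[str, list] = {}
    for h in all_hits:
        hits_by_tid.setdefault(h.sequence_id, []).append(h)

    families: list[GeneFamily] = []
    with open(path("trees.nhx.tsv")) as fh:
        for line in fh:
            if not line.strip():
                continue
            fam_id, newick = line.rstrip("\n").split("\t", 1)
            tree = parse_gene_tree(newick)
            transcripts: dict[str, list[Transcript]] = {}
            tree_transcript: dict[str, str] = {}
            fam_hits: list = []
            for tid, m in meta.items():
                if m["family"] != fam_id:
                    continue
                t = Transcript(
                    transcript_id=tid,
                    gene_id=m["gene"],
                    species=m["species"],
                    protein_sequence=sequences[tid],
                    exon_model=structures.get(tid),
                    chromosome=m["chromosome"],
                    genomic_span=m["span"],
                )
                transcripts.setdefault(m["gene"], []).append(t)
                if m["is_tree"]:
                    tree_transcript[m["gene"]] = tid
                fam_hits.extend(hits_by_tid.get(tid, []))
            families.append(
                GeneFamily(
                    family_id=fam_id,
                    tree=tree,
                    transcripts=transcripts,
                    hits=fam_hits,
                    tree_transcript=tree_transcript,
                )
            )

    proteome = [
        ProteomeEntry(
            protein_id=tid,
            gene_id=m["gene"],
            sequence=sequences[tid],
            chromosome=m["chromosome"],
            genomic_span=m["span"],
        )
        for tid, m in meta.items()
        if tid in sequences
    ]
    return Dataset(families, proteome, tracks, segdups, clan_map)


def events_table(classified: Sequence[ClassifiedEvent]) -> "pandas.DataFrame":
    """One row per classified event (TSV-ready)."""
    import pandas as pd

    rows = []
    for ce in classified:
        e, s = ce.event, ce.structure
        rows.append(
            {
                "family_id": e.family_id,
                "node": e.node_name,
                "characters": ",".join(e.character_ids),
                "representative": e.representative_transcript,
                "age_group": e.age_group,
                "parent_node_kind": e.parent_node_kind,
                "position": s.position,
                "exon_category": s.exon_category,
                "n_new_exons": s.n_new_exons,
                "symmetric_phases": s.symmetric_phase_flag,
                "mechanism": ce.mechanism.label,
                "mechanism_rule": ce.mechanism.rule,
                "donor_gene": ce.donor.donor_gene_id,
                "donor_same_chromosome": ce.donor.same_chromosome,
                "via_segdup": ce.donor.via_segdup,
            }
        )
    return pd.DataFrame(rows)
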