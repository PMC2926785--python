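"""Domain types and file I/O for the gain-inference pipeline.

Internal coordinates are 0-based half-open throughout; 1-based inclusive
coordinates appear only at file boundaries where the format dictates them
(GFF3, pfam_scan-style hit tables).

Formats handled here:

* Newick with NHX annotations (``D=Y|N`` duplication tags on internal nodes,
  ``S=<species>`` on leaves) for gene-family trees;
* GFF3 ``CDS`` features or a simplified per-transcript TSV for gene
  structures (exon spans in protein coordinates plus intron phases);
* pfam_scan-like TSV for domain hits;
* two-column TSV for the domain -> clan map;
* per-residue disorder-score TSV;
* FASTA for protein sequences (via Biopython);
* BEDPE for segmental-duplication interval pairs.
"""

from __future__ import annotations

import io
import itertools
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO


class FormatError(ValueError):
    """A file violated its documented format; message locates the problem."""


class ValidationError(ValueError):
    """An in-memory object violated a model invariant."""


# ---------------------------------------------------------------------------
# tree model
# ---------------------------------------------------------------------------

LEAF = "leaf"
SPECIATION = "speciation"
DUPLICATION = "duplication"


@dataclass
class TreeNode:
    """Node of a rooted gene-family tree.

    ``node_kind`` is ``leaf`` for tips and ``speciation``/``duplication`` for
    internal nodes (NHX ``D=N``/``D=Y``; a missing ``D`` tag is treated as
    speciation).  Leaves carry a non-empty ``species`` tag and their ``name``
    is the gene id.
    """

    name: str
    children: list["TreeNode"] = field(default_factory=list)
    branch_length: float = 0.0
    node_kind: str = SPECIATION
    species: str | None = None
    nhx_extra: dict[str, str] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterable["TreeNode"]:
        """Pre-order traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]


@dataclass
class GeneTree:
    """Rooted, NHX-labelled gene-family phylogeny."""

    root: TreeNode

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.walk():
            if node.branch_length < 0:
                raise ValidationError(
                    f"negative branch length on node {node.name!r}"
                )
            if node.is_leaf:
                if node.node_kind != LEAF:
                    raise ValidationError(
                        f"leaf {node.name!r} has node_kind {node.node_kind!r}"
                    )
                if not node.species:
                    raise ValidationError(f"leaf {node.name!r} lacks a species tag")
                if node.name in seen:
                    raise ValidationError(f"duplicate leaf id {node.name!r}")
                seen.add(node.name)
            else:
                if node.node_kind not in (SPECIATION, DUPLICATION):
                    raise ValidationError(
                        f"internal node {node.name!r} has kind {node.node_kind!r}"
                    )
                if len(node.children) < 2 and node is not self.root:
                    raise ValidationError(
                        f"internal node {node.name!r} has a single child"
                    )

    def nodes(self) -> list[TreeNode]:
        return list(self.root.walk())

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def parent_map(self) -> dict[int, TreeNode | None]:
        """Map ``id(node)`` -> parent node (None for the root)."""
        parents: dict[int, TreeNode | None] = {id(self.root): None}
        for node in self.root.walk():
            for child in node.children:
                parents[id(child)] = node
        return parents


_NHX_RE = re.compile(r"&&NHX(?P<body>(?::[^:\]]+)*)")


def _parse_nhx_comment(comments: Sequence[str]) -> dict[str, str]:
    tags: dict[str, str] = {}
    for comment in comments:
        m = _NHX_RE.search(comment)
        if not m:
            continue
        for item in m.group("body").split(":"):
            if not item:
                continue
            key, _, value = item.partition("=")
            tags[key] = value
    return tags


def parse_gene_tree(newick_nhx_text: str) -> GeneTree:
    """Parse a Newick/NHX string into a :class:`GeneTree`.

    NHX ``D=Y`` marks duplication nodes, ``D=N`` (or no tag) speciation;
    ``S=`` carries the species of a leaf.  Unknown NHX tags are preserved on
    the node but otherwise ignored.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_nhx_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            extract_comment_metadata=False,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"malformed Newick: {exc}") from exc

    counter = itertools.count()

    def convert(dnode: dendropy.Node) -> TreeNode:
        tags = _parse_nhx_comment(dnode.comments or [])
        children = [convert(c) for c in dnode.child_nodes()]
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        else:
            name = f"n{next(counter)}"
        node = TreeNode(
            name=name,
            children=children,
            branch_length=float(dnode.edge.length or 0.0),
        )
        if children:
            node.node_kind = DUPLICATION if tags.get("D") == "Y" else SPECIATION
        else:
            node.node_kind = LEAF
            node.species = tags.get("S")
        node.nhx_extra = {k: v for k, v in tags.items() if k not in ("D", "S")}
        return node

    root = convert(dtree.seed_node)
    return GeneTree(root)


def write_gene_tree(tree: GeneTree) -> str:
    """Serialize a :class:`GeneTree` back to Newick/NHX text."""

    def render(node: TreeNode) -> str:
        tags: list[str] = []
        if node.is_leaf:
            body = node.name
            if node.species:
                tags.append(f"S={node.species}")
        else:
            body = (
                "(" + ",".join(render(c) for c in node.children) + ")"
                + node.name
            )
            tags.append("D=" + ("Y" if node.node_kind == DUPLICATION else "N"))
        tags.extend(f"{k}={v}" for k, v in sorted(node.nhx_extra.items()))
        nhx = f"[&&NHX:{':'.join(tags)}]" if tags else ""
        return f"{body}{nhx}:{node.branch_length:.9g}"

    # no branch length after the root
    root = tree.root
    if root.is_leaf:
        return f"({render(root)});"
    return (
        "(" + ",".join(render(c) for c in root.children) + ")" + root.name
        + "[&&NHX:D=%s]" % ("Y" if root.node_kind == DUPLICATION else "N")
        + ";"
    )


# ---------------------------------------------------------------------------
# gene structure
# ---------------------------------------------------------------------------


@dataclass
class ExonModel:
    """Exon spans of one transcript in protein coordinates, with phases.

    ``exons`` are ordered, contiguous, non-overlapping 0-based half-open
    spans covering ``[0, protein_length)``.  ``phases[i]`` is the intron
    phase at the junction between exon ``i`` and exon ``i+1``: the number of
    nucleotides the upstream exon carries into the split codon (0 means the
    intron falls on a codon boundary).
    """

    exons: tuple[tuple[int, int], ...]
    phases: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError("exon model must contain at least one exon")
        if len(self.phases) != len(self.exons) - 1:
            raise ValidationError("need exactly one phase per internal junction")
        prev_end = 0
        for start, end in self.exons:
            if start != prev_end or end <= start:
                raise ValidationError(
                    f"exon spans must be contiguous half-open, got {self.exons}"
                )
            prev_end = end
        if any(p not in (0, 1, 2) for p in self.phases):
            raise ValidationError(f"phases must be 0/1/2, got {self.phases}")
        if self.exons[0][0] != 0:
            raise ValidationError("first exon must start at 0")

    @property
    def protein_length(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class Transcript:
    """One splice form: protein sequence, genomic metadata, exon model."""

    transcript_id: str
    gene_id: str
    species: str
    protein_sequence: str
    exon_model: ExonModel | None = None
    chromosome: str | None = None
    strand: str = "+"
    genomic_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.exon_model is not None and (
            self.exon_model.protein_length != len(self.protein_sequence)
        ):
            raise ValidationError(
                f"{self.transcript_id}: exon model covers "
                f"{self.exon_model.protein_length} aa but protein is "
                f"{len(self.protein_sequence)} aa"
            )


@dataclass
class DomainHit:
    """A domain-model match on one protein (pfam_scan-style).

    ``character_id`` is the evolutionary character used by parsimony: the
    clan id once clan mapping is applied, else the domain id.
    """

    sequence_id: str
    domain_id: str
    start: int
    end: int
    e_value: float
    model_coverage: float
    clan_id: str | None = None
    provenance: str = "pfam"  # or "rescued"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"{self.sequence_id}/{self.domain_id}: bad envelope "
                f"[{self.start}, {self.end})"
            )
        if self.e_value <= 0:
            raise ValidationError(
                f"{self.sequence_id}/{self.domain_id}: E-value must be > 0"
            )
        if not 0.0 <= self.model_coverage <= 1.0:
            raise ValidationError(
                f"{self.sequence_id}/{self.domain_id}: model coverage "
                f"{self.model_coverage} outside [0, 1]"
            )

    @property
    def character_id(self) -> str:
        return self.clan_id if self.clan_id else self.domain_id


@dataclass
class DisorderTrack:
    """Per-residue disorder scores in [0, 1] for one protein."""

    sequence_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        bad = [s for s in self.scores if not 0.0 <= s <= 1.0]
        if bad:
            raise ValidationError(
                f"{self.sequence_id}: disorder scores outside [0, 1]: {bad[:3]}"
            )

    def disordered_fraction(self, start: int, end: int, cutoff: float) -> float:
        window = self.scores[start:end]
        if not window:
            return 0.0
        return sum(1 for s in window if s >= cutoff) / len(window)


@dataclass
class GeneFamily:
    """A gene family: labelled tree, transcripts per gene, domain hits."""

    family_id: str
    tree: GeneTree
    transcripts: dict[str, list[Transcript]]
    hits: list[DomainHit]
    tree_transcript: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene_id in self.transcripts:
            self.tree_transcript.setdefault(
                gene_id, self.transcripts[gene_id][0].transcript_id
            )
        self.validate()

    def validate(self) -> None:
        for leaf in self.tree.leaf_names():
            if leaf not in self.transcripts or not self.transcripts[leaf]:
                raise ValidationError(
                    f"family {self.family_id}: tree leaf {leaf!r} has no transcript"
                )
        known = {t.transcript_id for ts in self.transcripts.values() for t in ts}
        for hit in self.hits:
            if hit.sequence_id not in known:
                raise ValidationError(
                    f"family {self.family_id}: hit on unknown sequence "
                    f"{hit.sequence_id!r}"
                )

    # -- convenience lookups -------------------------------------------------

    def transcript(self, transcript_id: str) -> Transcript:
        for ts in self.transcripts.values():
            for t in ts:
                if t.transcript_id == transcript_id:
                    return t
        raise KeyError(transcript_id)

    def tree_transcript_of(self, gene_id: str) -> Transcript:
        return self.transcript(self.tree_transcript[gene_id])

    def all_transcripts(self) -> list[Transcript]:
        return [t for ts in self.transcripts.values() for t in ts]

    def hits_on(self, transcript_id: str) -> list[DomainHit]:
        return [h for h in self.hits if h.sequence_id == transcript_id]

    def characters(self) -> set[str]:
        return {h.character_id for h in self.hits}


# ---------------------------------------------------------------------------
# gene-structure readers
# ---------------------------------------------------------------------------


def _structures_from_tsv(lines: Iterable[str], source: str) -> dict[str, ExonModel]:
    """Simplified structure dialect (documented in the README):

    ``transcript_id <TAB> exon spans <TAB> phases`` with spans as
    comma-separated ``start-end`` pairs in protein coordinates (0-based
    half-open) and phases as comma-separated digits (``-`` when the
    transcript has a single exon).  Lines starting with ``#`` are skipped.
    """
    models: dict[str, ExonModel] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{source}:{lineno}: expected 3 tab-separated fields")
        tid, span_field, phase_field = parts
        try:
            exons = tuple(
                (int(a), int(b))
                for a, b in (span.split("-") for span in span_field.split(","))
            )
            phases = (
                tuple()
                if phase_field in ("-", "")
                else tuple(int(p) for p in phase_field.split(","))
            )
        except ValueError as exc:
            raise FormatError(f"{source}:{lineno}: {exc}") from exc
        try:
            models[tid] = ExonModel(exons, phases)
        except ValidationError as exc:
            raise FormatError(f"{source}:{lineno}: {exc}") from exc
    return models


def _structures_from_gff3(path: str) -> dict[str, ExonModel]:
    """Project GFF3 CDS features into protein-coordinate exon models.

    Minus-strand CDS are assembled 5'->3' of the transcript before the
    projection, so exon order always follows the protein.  The phase at
    junction *i* equals the cumulative CDS nucleotide length mod 3.
    """
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    by_transcript: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID")
        if not parents:
            raise FormatError(f"CDS at {cds.seqid}:{cds.start} lacks Parent/ID")
        by_transcript.setdefault(parents[0], []).append(cds)

    models: dict[str, ExonModel] = {}
    for tid, features in by_transcript.items():
        strand = features[0].strand
        features.sort(key=lambda f: f.start, reverse=(strand == "-"))
        spans_nt = []
        for f in features:
            if spans_nt and strand == "+" and f.start <= spans_nt[-1][1]:
                raise FormatError(f"{tid}: overlapping CDS features")
            if spans_nt and strand == "-" and f.end >= spans_nt[-1][0]:
                raise FormatError(f"{tid}: overlapping CDS features")
            spans_nt.append((f.start, f.end))  # GFF3 is 1-based inclusive
        lengths = [end - start + 1 for start, end in spans_nt]
        total = sum(lengths)
        if total % 3 != 0:
            raise FormatError(
                f"{tid}: CDS length {total} is not a multiple of 3"
            )
        exons: list[tuple[int, int]] = []
        phases: list[int] = []
        cum = 0
        for i, nt in enumerate(lengths):
            start_aa = cum // 3
            cum += nt
            # half-open protein span; a codon split across the junction
            # belongs to the exon carrying its first nucleotide(s)
            end_aa = (cum + 2) // 3
            exons.append((start_aa, end_aa))
            if i < len(lengths) - 1:
                phases.append(cum % 3)
        # enforce contiguity: a split codon is assigned to the upstream exon
        fixed: list[tuple[int, int]] = []
        prev_end = 0
        for start_aa, end_aa in exons:
            fixed.append((prev_end, max(end_aa, prev_end + 1)))
            prev_end = fixed[-1][1]
        models[tid] = ExonModel(tuple(fixed), tuple(phases))
    return models


def read_gene_structure(path_or_buffer) -> dict[str, ExonModel]:
    """Read exon models from GFF3 (``.gff``/``.gff3``) or the simplified TSV.

    Returns a map ``transcript_id -> ExonModel``.
    """
    if hasattr(path_or_buffer, "read"):
        return _structures_from_tsv(path_or_buffer, source="<buffer>")
    path = os.fspath(path_or_buffer)
    if path.endswith((".gff", ".gff3")):
        return _structures_from_gff3(path)
    with open(path) as fh:
        return _structures_from_tsv(fh, source=path)


def write_gene_structure(models: Mapping[str, ExonModel]) -> str:
    """Render exon models in the simplified TSV dialect."""
    out = io.StringIO()
    out.write("#transcript_id\texons\tphases\n")
    for tid in sorted(models):
        m = models[tid]
        spans = ",".join(f"{a}-{b}" for a, b in m.exons)
        phases = ",".join(str(p) for p in m.phases) if m.phases else "-"
        out.write(f"{tid}\t{spans}\t{phases}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# flat-table readers
# ---------------------------------------------------------------------------


def read_domain_hits(path_or_buffer) -> list[DomainHit]:
    """Read a pfam_scan-style hit table.

    Columns (tab-separated): sequence id, domain id, envelope start, envelope
    end (1-based inclusive as printed by pfam_scan), E-value, model coverage,
    and optionally clan id and provenance.  Coordinates are converted to
    0-based half-open.
    """
    lines, source = _as_lines(path_or_buffer)
    hits: list[DomainHit] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise FormatError(f"{source}:{lineno}: expected >= 6 fields")
        seq_id, dom_id, start_s, end_s, ev_s, cov_s = parts[:6]
        clan = parts[6] if len(parts) > 6 and parts[6] not in ("", "-") else None
        prov = parts[7] if len(parts) > 7 and parts[7] else "pfam"
        try:
            start1, end1 = int(start_s), int(end_s)
            e_value, coverage = float(ev_s), float(cov_s)
        except ValueError as exc:
            raise FormatError(f"{source}:{lineno}: {exc}") from exc
        if end1 < start1:
            raise FormatError(f"{source}:{lineno}: envelope end before start")
        try:
            hits.append(
                DomainHit(
                    sequence_id=seq_id,
                    domain_id=dom_id,
                    start=start1 - 1,
                    end=end1,
                    e_value=e_value,
                    model_coverage=coverage,
                    clan_id=clan,
                    provenance=prov,
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{source}:{lineno}: {exc}") from exc
    return hits


def write_domain_hits(hits: Sequence[DomainHit]) -> str:
    out = io.StringIO()
    out.write("#sequence_id\tdomain_id\tstart\tend\te_value\tmodel_coverage"
              "\tclan_id\tprovenance\n")
    for h in hits:
        out.write(
            f"{h.sequence_id}\t{h.domain_id}\t{h.start + 1}\t{h.end}\t"
            f"{h.e_value:.3g}\t{h.model_coverage:.3f}\t{h.clan_id or '-'}\t"
            f"{h.provenance}\n"
        )
    return out.getvalue()


def read_clan_map(path_or_buffer) -> dict[str, str]:
    """Read a two-column TSV ``domain_id -> clan_id`` (partial map is fine)."""
    lines, source = _as_lines(path_or_buffer)
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{source}:{lineno}: expected 2 fields")
        mapping[parts[0]] = parts[1]
    return mapping


def read_disorder_track(path_or_buffer, sequence_id: str | None = None,
                        protein_length: int | None = None) -> DisorderTrack:
    """Read one per-residue disorder track (``sequence_id <TAB> score`` rows,
    or one bare score per line when ``sequence_id`` is given).
    """
    lines, source = _as_lines(path_or_buffer)
    scores: list[float] = []
    sid = sequence_id
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            value = parts[0]
        else:
            if sid is None:
                sid = parts[0]
            elif parts[0] != sid:
                raise FormatError(
                    f"{source}:{lineno}: mixed sequence ids in one track"
                )
            value = parts[1]
        try:
            score = float(value)
        except ValueError as exc:
            raise FormatError(f"{source}:{lineno}: {exc}") from exc
        if not 0.0 <= score <= 1.0:
            raise FormatError(
                f"{source}:{lineno}: disorder score {score} outside [0, 1]"
            )
        scores.append(score)
    if sid is None:
        raise FormatError(f"{source}: no sequence id for disorder track")
    track = DisorderTrack(sid, tuple(scores))
    if protein_length is not None and len(scores) != protein_length:
        raise ValidationError(
            f"{sid}: track has {len(scores)} scores for a "
            f"{protein_length}-aa protein"
        )
    return track


def read_disorder_tracks(path_or_buffer) -> dict[str, DisorderTrack]:
    """Read many tracks from one ``sequence_id <TAB> score`` TSV."""
    lines, source = _as_lines(path_or_buffer)
    per_seq: dict[str, list[float]] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{source}:{lineno}: expected 2 fields")
        try:
            score = float(parts[1])
        except ValueError as exc:
            raise FormatError(f"{source}:{lineno}: {exc}") from exc
        if not 0.0 <= score <= 1.0:
            raise FormatError(
                f"{source}:{lineno}: disorder score {score} outside [0, 1]"
            )
        per_seq.setdefault(parts[0], []).append(score)
    return {sid: DisorderTrack(sid, tuple(s)) for sid, s in per_seq.items()}


def read_fasta(path_or_buffer) -> dict[str, str]:
    """Read protein FASTA into ``id -> sequence`` (Biopython parser)."""
    handle = path_or_buffer if hasattr(path_or_buffer, "read") else open(path_or_buffer)
    try:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if handle is not path_or_buffer:
            handle.close()


@dataclass(frozen=True)
class SegDupPair:
    """One segmental-duplication pair (BEDPE row, 0-based half-open)."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int


def read_segdup_pairs(path_or_buffer) -> list[SegDupPair]:
    """Read segmental-duplication interval pairs from BEDPE."""
    lines, source = _as_lines(path_or_buffer)
    pairs: list[SegDupPair] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise FormatError(f"{source}:{lineno}: BEDPE needs >= 6 fields")
        try:
            pairs.append(
                SegDupPair(
                    parts[0], int(parts[1]), int(parts[2]),
                    parts[3], int(parts[4]), int(parts[5]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{source}:{lineno}: {exc}") from exc
    return pairs


def _as_lines(path_or_buffer) -> tuple[list[str], str]:
    if hasattr(path_or_buffer, "read"):
        return list(path_or_buffer), "<buffer>"
    path = os.fspath(path_or_buffer)
    with open(path) as fh:
        return list(fh), path
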