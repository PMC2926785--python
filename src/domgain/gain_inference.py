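"""Gene-level presence coding, weighted parsimony, and the gain funnel.

The central inference is weighted (Sankoff) parsimony on a binary
presence/absence character over each gene-family tree, with a domain gain
(0 -> 1 along an edge) costing 2 and a loss (1 -> 0) costing 1.  Because a
gain costs more than a loss, the reconstruction prefers explaining patchy
presence by ancestral presence plus losses, so the gains that survive are
conservative calls.  A Dollo-concordance screen then keeps a character's
gains only when the tree reports exactly one gain of it, and gains on
terminal edges (a single annotated sequence) are discarded as likely
annotation artifacts.

Tie rule: among minimum-cost labellings, the one with fewer gains is chosen
(a labelling without a gain beats a tying labelling with one), then fewer
total events, then present-at-node; this makes the event list deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .config import (
    DEFAULT_CLADE_MAP,
    QUALITY_SPECIES,
    ScoringConfig,
    ThresholdConfig,
)
from .io_model import DUPLICATION, GeneFamily, GeneTree, TreeNode, ValidationError
from .refinement import residue_profile


# ---------------------------------------------------------------------------
# presence coding
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Binary presence of each character on each leaf gene.

    Presence is the union over all splice variants of the gene, and is
    blind to hit provenance (rescued hits count like original ones).
    """

    genes: tuple[str, ...]
    characters: tuple[str, ...]
    data: dict[tuple[str, str], int]

    def state(self, gene_id: str, character_id: str) -> int:
        return self.data.get((gene_id, character_id), 0)


def leaf_presence_matrix(family: GeneFamily) -> PresenceMatrix:
    """Code presence/absence of every character for every tree leaf."""
    genes = tuple(family.tree.leaf_names())
    for g in genes:
        if not family.transcripts.get(g):
            raise ValidationError(f"gene {g!r} has no transcripts")
    transcript_gene = {
        t.transcript_id: g for g, ts in family.transcripts.items() for t in ts
    }
    data: dict[tuple[str, str], int] = {}
    chars: set[str] = set()
    for hit in family.hits:
        gene = transcript_gene[hit.sequence_id]
        chars.add(hit.character_id)
        data[(gene, hit.character_id)] = 1
    return PresenceMatrix(genes, tuple(sorted(chars)), data)


# ---------------------------------------------------------------------------
# Sankoff reconstruction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateChange:
    """A state change on the edge into ``node`` (gain: 0->1, loss: 1->0)."""

    family_id: str
    character_id: str
    node_name: str
    kind: str  # "gain" | "loss"


@dataclass
class Reconstruction:
    states: dict[str, int]  # node name -> 0/1
    events: list[StateChange]
    cost: float


def sankoff_reconstruct(
    tree: GeneTree,
    presence: PresenceMatrix,
    character_id: str,
    cfg: ThresholdConfig | None = None,
    family_id: str = "",
) -> Reconstruction:
    """Minimum-cost ancestral labelling of one binary character.

    Edge costs: 0->1 costs ``cfg.gain_cost``, 1->0 costs ``cfg.loss_cost``,
    no cost for keeping the state.  Both root states carry zero prior cost.
    Ties are broken toward fewer gains, then fewer events, then presence.
    """
    cfg = cfg or ThresholdConfig()

    def edge_cost(parent: int, child: int) -> tuple[float, int, int]:
        if parent == child:
            return (0.0, 0, 0)
        if parent == 0:  # gain
            return (cfg.gain_cost, 1, 1)
        return (cfg.loss_cost, 0, 1)  # loss

    # bottom-up: per node, per state, (cost, n_gains, n_events) lexicographic
    table: dict[int, dict[int, tuple[float, int, int]]] = {}
    choice: dict[int, dict[int, dict[int, int]]] = {}  # node -> state -> child -> child state

    def visit(node: TreeNode) -> None:
        for child in node.children:
            visit(child)
        if node.is_leaf:
            leaf_state = presence.state(node.name, character_id)
            table[id(node)] = {
                0: (0.0, 0, 0) if leaf_state == 0 else (float("inf"), 0, 0),
                1: (0.0, 0, 0) if leaf_state == 1 else (float("inf"), 0, 0),
            }
            return
        table[id(node)] = {}
        choice[id(node)] = {}
        for s in (0, 1):
            total = (0.0, 0, 0)
            picks: dict[int, int] = {}
            for child in node.children:
                best: tuple[float, int, int] | None = None
                best_state = 0
                for t in (0, 1):
                    c_cost, c_gain, c_ev = table[id(child)][t]
                    e_cost, e_gain, e_ev = edge_cost(s, t)
                    cand = (c_cost + e_cost, c_gain + e_gain, c_ev + e_ev)
                    # tie-break prefers the child state matching the parent
                    # (no event), realised by comparing (cost, gains, events)
                    if best is None or cand < best:
                        best = cand
                        best_state = t
                assert best is not None
                total = (
                    total[0] + best[0],
                    total[1] + best[1],
                    total[2] + best[2],
                )
                picks[id(child)] = best_state
            table[id(node)][s] = total
            choice[id(node)][s] = picks

    root = tree.root
    visit(root)
    root_costs = table[id(root)]
    # tie between root states: fewer gains, then fewer events, then absent
    root_state = min((0, 1), key=lambda s: (root_costs[s], s))

    states: dict[str, int] = {}
    events: list[StateChange] = []

    def assign(node: TreeNode, state: int) -> None:
        states[node.name] = state
        if node.is_leaf:
            return
        for child in node.children:
            t = choice[id(node)][state][id(child)]
            if t != state:
                events.append(
                    StateChange(
                        family_id=family_id,
                        character_id=character_id,
                        node_name=child.name,
                        kind="gain" if t == 1 else "loss",
                    )
                )
            assign(child, t)

    if root_costs[root_state][0] == float("inf"):
        # character absent from every leaf: all-absent labelling, no events
        for node in root.walk():
            states[node.name] = 0
        return Reconstruction(states, [], 0.0)
    assign(root, root_state)
    return Reconstruction(states, events, root_costs[root_state][0])


# ---------------------------------------------------------------------------
# event filters
# ---------------------------------------------------------------------------


def dollo_concordance(events: Sequence[StateChange]) -> list[StateChange]:
    """Keep a character's gains only when exactly one gain of that character
    is reported in the tree; losses pass through untouched."""
    gain_counts: dict[str, int] = {}
    for e in events:
        if e.kind == "gain":
            gain_counts[e.character_id] = gain_counts.get(e.character_id, 0) + 1
    return [
        e
        for e in events
        if e.kind != "gain" or gain_counts[e.character_id] == 1
    ]


def exclude_leaf_gains(
    events: Sequence[StateChange], tree: GeneTree
) -> list[StateChange]:
    """Drop gains whose edge subtends a single leaf (one annotated sequence)."""
    leaf_names = set(tree.leaf_names())
    return [
        e
        for e in events
        if e.kind != "gain" or e.node_name not in leaf_names
    ]


# ---------------------------------------------------------------------------
# gain events and the funnel
# ---------------------------------------------------------------------------


@dataclass
class GainEvent:
    """A high-confidence candidate domain gain on an internal tree node."""

    family_id: str
    character_ids: tuple[str, ...]
    node_name: str
    parent_node_kind: str  # duplication | speciation
    descendant_genes: tuple[str, ...]
    descendant_species: tuple[str, ...]
    representative_transcript: str | None = None
    age_group: str | None = None
    filter_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def character_id(self) -> str:
        return self.character_ids[0]


def _find_node(tree: GeneTree, name: str) -> TreeNode:
    for node in tree.root.walk():
        if node.name == name:
            return node
    raise KeyError(name)


def make_gain_event(
    family: GeneFamily, change: StateChange
) -> GainEvent:
    node = _find_node(family.tree, change.node_name)
    parents = family.tree.parent_map()
    parent = parents[id(node)]
    parent_kind = parent.node_kind if parent is not None else family.tree.root.node_kind
    if parent_kind == DUPLICATION:
        kind = DUPLICATION
    else:
        kind = "speciation"
    leaves = node.leaves()
    return GainEvent(
        family_id=family.family_id,
        character_ids=(change.character_id,),
        node_name=change.node_name,
        parent_node_kind=kind,
        descendant_genes=tuple(l.name for l in leaves),
        descendant_species=tuple(l.species for l in leaves),
    )


def select_representative(
    event: GainEvent,
    family: GeneFamily,
    quality_species: Iterable[str] = QUALITY_SPECIES,
    preferred_species: str = "human",
) -> str | None:
    """Choose the representative transcript for a gain event.

    Eligible transcripts must (a) be their gene's tree transcript, (b) carry
    a direct (non-rescued) hit for the gained character, and (c) belong to a
    quality-genome species.  The preferred species (human) wins when
    available; remaining ties break lexicographically on transcript id.
    Returns ``None`` when no transcript qualifies (the event is rejected).
    """
    quality = set(quality_species)
    direct = {
        h.sequence_id
        for h in family.hits
        if h.character_id in event.character_ids and h.provenance != "rescued"
    }
    candidates = []
    for gene in event.descendant_genes:
        t = family.tree_transcript_of(gene)
        if t.transcript_id in direct and t.species in quality:
            candidates.append(t)
    if not candidates:
        return None
    candidates.sort(
        key=lambda t: (t.species != preferred_species, t.transcript_id)
    )
    return candidates[0].transcript_id


def similarity_exclusion(
    event: GainEvent,
    family: GeneFamily,
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
) -> bool:
    """True (keep) unless the gained-domain sequence shares >= 16% identical
    aligned residues (relative to the domain length) with any family sequence
    that lacks the gained character — evidence the "gain" may be a missed
    annotation rather than a real acquisition.

    Identity is read from a full-length alignment of the representative
    against each domain-lacking sequence (global with free end gaps, the
    pairwise analogue of a family alignment), restricted to the gained-domain
    span: the ancestral context anchors the alignment so that residues of a
    genuinely novel insertion fall in gap columns.
    """
    cfg = cfg or ThresholdConfig()
    if event.representative_transcript is None:
        return False
    rep = family.transcript(event.representative_transcript)
    spans = [
        (h.start, h.end)
        for h in family.hits
        if h.sequence_id == rep.transcript_id
        and h.character_id in event.character_ids
    ]
    if not spans:
        return False
    start = min(s for s, _ in spans)
    end = max(e for _, e in spans)
    if end <= start:
        return False
    domain_len = end - start

    with_char = {
        h.sequence_id for h in family.hits
        if h.character_id in event.character_ids
    }
    lacking = [
        t for t in family.all_transcripts() if t.transcript_id not in with_char
    ]
    for t in lacking:
        _, identical = residue_profile(
            rep.protein_sequence, t.protein_sequence, scoring
        )
        if sum(identical[start:end]) / domain_len >= cfg.exclusion_identity:
            return False
    return True


def group_simultaneous_gains(events: Sequence[GainEvent]) -> list[GainEvent]:
    """Merge characters gained on the same node of the same family into one
    event (domains gained together count as a single gain event)."""
    grouped: dict[tuple[str, str], GainEvent] = {}
    order: list[tuple[str, str]] = []
    for e in events:
        key = (e.family_id, e.node_name)
        if key in grouped:
            g = grouped[key]
            g.character_ids = tuple(sorted(set(g.character_ids + e.character_ids)))
        else:
            grouped[key] = GainEvent(
                family_id=e.family_id,
                character_ids=e.character_ids,
                node_name=e.node_name,
                parent_node_kind=e.parent_node_kind,
                descendant_genes=e.descendant_genes,
                descendant_species=e.descendant_species,
                representative_transcript=e.representative_transcript,
                age_group=e.age_group,
                filter_flags=dict(e.filter_flags),
            )
            order.append(key)
    return [grouped[k] for k in order]


def assign_age_group(
    event: GainEvent,
    clade_map: Sequence[tuple[str, frozenset[str]]] = DEFAULT_CLADE_MAP,
) -> str:
    """Smallest configured clade containing every descendant species."""
    species = set(event.descendant_species)
    known = set().union(*(s for _, s in clade_map))
    unknown = species - known
    if unknown:
        raise ValueError(f"species not in clade map: {sorted(unknown)}")
    for name, members in clade_map:
        if species <= members:
            return name
    raise ValueError("clade map does not cover the species set")  # pragma: no cover


# ---------------------------------------------------------------------------
# the funnel
# ---------------------------------------------------------------------------

FUNNEL_STAGES = (
    "concordant_gains",
    "internal_node_gains",
    "with_representative",
    "after_similarity_exclusion",
    "grouped_events",
    "after_blacklist",
)


@dataclass
class FamilyGainResult:
    events: list[GainEvent]
    stage_counts: dict[str, int]
    losses: list[StateChange]


def infer_family_gains(
    family: GeneFamily,
    cfg: ThresholdConfig | None = None,
    scoring: ScoringConfig | None = None,
    quality_species: Iterable[str] = QUALITY_SPECIES,
    preferred_species: str = "human",
    clade_map: Sequence[tuple[str, frozenset[str]]] = DEFAULT_CLADE_MAP,
    blacklist: Iterable[tuple[str, str]] = (),
) -> FamilyGainResult:
    """Run the full gain-calling funnel on one refined family.

    Stages (each a subset of the previous): Sankoff gains concordant with
    Dollo's single-origin rule; gains on internal nodes; gains with an
    eligible representative transcript; gains surviving the 16% similarity
    screen; grouping of same-node characters into events; removal of
    user-blacklisted (family, node) pairs.
    """
    cfg = cfg or ThresholdConfig()
    presence = leaf_presence_matrix(family)
    all_events: list[StateChange] = []
    for char in presence.characters:
        rec = sankoff_reconstruct(
            family.tree, presence, char, cfg, family_id=family.family_id
        )
        all_events.extend(rec.events)

    losses = [e for e in all_events if e.kind == "loss"]
    concordant = [
        e for e in dollo_concordance(all_events) if e.kind == "gain"
    ]
    counts = {"concordant_gains": len(concordant)}

    internal = [
        e for e in exclude_leaf_gains(concordant, family.tree) if e.kind == "gain"
    ]
    counts["internal_node_gains"] = len(internal)

    with_rep: list[GainEvent] = []
    for change in internal:
        ev = make_gain_event(family, change)
        rep = select_representative(ev, family, quality_species, preferred_species)
        ev.filter_flags["has_representative"] = rep is not None
        if rep is not None:
            ev.representative_transcript = rep
            with_rep.append(ev)
    counts["with_representative"] = len(with_rep)

    surviving: list[GainEvent] = []
    for ev in with_rep:
        keep = similarity_exclusion(ev, family, cfg, scoring)
        ev.filter_flags["passes_similarity_exclusion"] = keep
        if keep:
            surviving.append(ev)
    counts["after_similarity_exclusion"] = len(surviving)

    grouped = group_simultaneous_gains(surviving)
    counts["grouped_events"] = len(grouped)

    black = set(blacklist)
    final = [
        e for e in grouped if (e.family_id, e.node_name) not in black
    ]
    counts["after_blacklist"] = len(final)

    for ev in final:
        ev.age_group = assign_age_group(ev, clade_map)

    return FamilyGainResult(events=final, stage_counts=counts, losses=losses)


def merge_stage_counts(results: Iterable[FamilyGainResult]) -> dict[str, int]:
    totals = {stage: 0 for stage in FUNNEL_STAGES}
    for r in results:
        for stage, n in r.stage_counts.items():
            totals[stage] += n
    return totals
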