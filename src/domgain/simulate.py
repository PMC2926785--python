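"""Synthetic gene-family generator with mechanism-labelled planted gains.

Each simulated family is a rooted, NHX-labelled gene tree with an ancestral
multi-exon protein architecture shared by all leaves, plus one planted
domain-gain event on a deep internal node.  The inserted coding structure
realizes the planted mechanism:

* retroposition — the gained domain occupies exactly one novel exon in the
  middle of the protein, flanking intron phases differ, and a multi-exon
  donor gene carrying the same domain exists elsewhere in the proteome;
* adjacent_gene_joining — the domain is coded by two novel exons appended
  at a protein terminus, with a donor gene adjacent on the same chromosome
  (optionally supported by a segmental-duplication pair);
* intronic_insertion — two novel exons are inserted into an ancestral
  intron; both flanking introns keep the ancestral phase (symmetric);
* exonization — an ancestral terminal exon is extended with the domain
  sequence, no new exons are created, the gained segment carries high
  intrinsic-disorder scores, and no donor exists.

Domain blocks are distinct high-entropy sequences so that the pipeline's
identity thresholds discriminate as designed; substitution noise is applied
per branch at a configurable per-site rate.  Everything is deterministic
given the seed.  The generator targets the pipeline's decision boundaries,
not realistic sequence evolution (no indels, no codon model).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import DEFAULT_CLADE_MAP
from .io_model import (
    DisorderTrack,
    DomainHit,
    ExonModel,
    GeneFamily,
    GeneTree,
    SegDupPair,
    Transcript,
    TreeNode,
    write_domain_hits,
    write_gene_structure,
    write_gene_tree,
)
from .mechanism_donor import (
    ADJACENT_JOINING,
    EXONIZATION,
    INTRONIC_INSERTION,
    RETROPOSITION,
    ProteomeEntry,
)
from .structure_classification import (
    AMINO,
    CARBOXY,
    EXTENSION_ONLY,
    MIDDLE,
    MULTIPLE_NEW,
    SINGLE_NEW,
    StructureCall,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: natural amino-acid background frequencies (Robinson & Robinson, as used
#: for BLOSUM62 significance statistics); sequences drawn from this
#: composition behave like real proteins under the aligner's E-values
_AA_FREQ = np.array([
    0.078, 0.019, 0.054, 0.063, 0.039, 0.074, 0.022, 0.051, 0.057, 0.090,
    0.022, 0.045, 0.052, 0.043, 0.051, 0.071, 0.058, 0.064, 0.013, 0.032,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

#: species pools for the gain clade, by target age group (human always included
#: so a quality-genome representative exists)
_GAIN_CLADE_POOLS: dict[str, tuple[str, ...]] = {
    "primates": ("chimp", "macaque"),
    "mammals": ("mouse", "rat", "dog", "cow"),
    "vertebrates": ("zebrafish", "chicken", "frog", "fugu"),
    "bilateria": ("fruit_fly", "mosquito", "worm"),
    "animals": ("sea_anemone", "sponge"),
}

_OUTGROUP_SPECIES = (
    "zebrafish", "frog", "fruit_fly", "worm", "sea_anemone", "sponge",
    "mosquito", "fugu",
)

MECHANISMS_IN_MIX = (RETROPOSITION, ADJACENT_JOINING, INTRONIC_INSERTION,
                     EXONIZATION)


@dataclass
class SimulationConfig:
    """Knobs of the generator; the defaults are the conditions used
    throughout the test-suite and the reproduction script.

    ``mechanism_mix`` is the proportion of families planted with each
    mechanism, in the order (retroposition, adjacent_gene_joining,
    intronic_insertion, exonization).  ``loss_probability`` applies per
    branch below the planted gain node.  ``substitution_probability`` is the
    per-site, per-branch amino-acid substitution rate.
    """

    seed: int = 0
    n_families: int = 50
    duplication_probability: float = 0.3
    n_outgroups: tuple[int, int] = (3, 5)      # min/max spine outgroups
    gain_clade_leaves: tuple[int, int] = (2, 4)
    domain_inventory_size: int = 40
    domain_length: int = 80
    ancestral_exon_lengths: tuple[int, ...] = (40, 50, 45, 40)
    loss_probability: float = 0.0
    mechanism_mix: tuple[float, float, float, float] = (0.1, 0.5, 0.2, 0.2)
    substitution_probability: float = 0.0
    segdup_fraction: float = 0.5
    disorder_mean_exonized: float = 0.8
    disorder_mean_background: float = 0.1

    def __post_init__(self) -> None:
        if abs(sum(self.mechanism_mix) - 1.0) > 1e-9:
            raise ValueError("mechanism mix must sum to 1")
        for p in (
            self.duplication_probability,
            self.loss_probability,
            self.substitution_probability,
            self.segdup_fraction,
            *self.mechanism_mix,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if len(self.ancestral_exon_lengths) < 3:
            raise ValueError(
                "intronic insertion needs hosts with at least 3 exons"
            )


@dataclass
class PlantedEvent:
    """Ground truth for one planted gain."""

    family_id: str
    gain_node: str
    character_id: str
    mechanism: str
    donor_gene_id: str | None
    structure: StructureCall
    age_group: str
    donor_same_chromosome: bool | None = None
    lost_leaves: tuple[str, ...] = ()


@dataclass
class SimulatedDataset:
    families: list[GeneFamily]
    proteome: list[ProteomeEntry]
    tracks: dict[str, DisorderTrack]
    segdups: list[SegDupPair]
    clan_map: dict[str, str]
    truth: list[PlantedEvent]
    config: SimulationConfig

    def write(self, out_dir: str) -> None:
        """Emit every pipeline input format (all plain text)."""
        os.makedirs(out_dir, exist_ok=True)
        trees, structures, hit_rows, fasta, meta = [], {}, [], [], []
        for fam in self.families:
            trees.append(f"{fam.family_id}\t{write_gene_tree(fam.tree)}")
            for t in fam.all_transcripts():
                structures[t.transcript_id] = t.exon_model
                span = t.genomic_span or (0, 0)
                meta.append(
                    f"{t.transcript_id}\t{t.gene_id}\t{fam.family_id}\t"
                    f"{t.species}\t{t.chromosome}\t{span[0]}\t{span[1]}\t"
                    f"{int(fam.tree_transcript[t.gene_id] == t.transcript_id)}"
                )
            hit_rows.extend(fam.hits)
        for entry in self.proteome:
            fasta.append(
                f">{entry.protein_id} gene={entry.gene_id} "
                f"chrom={entry.chromosome} "
                f"span={entry.genomic_span[0]}-{entry.genomic_span[1]}"
            )
            fasta.append(entry.sequence)
            if entry.protein_id not in structures:
                meta.append(
                    f"{entry.protein_id}\t{entry.gene_id}\t-\t-\t"
                    f"{entry.chromosome}\t{entry.genomic_span[0]}\t"
                    f"{entry.genomic_span[1]}\t0"
                )

        def put(name: str, text: str) -> None:
            with open(os.path.join(out_dir, name), "w") as fh:
                fh.write(text)

        put("trees.nhx.tsv", "\n".join(trees) + "\n")
        put("structures.tsv", write_gene_structure(structures))
        put("hits.tsv", write_domain_hits(hit_rows))
        put("proteome.fasta", "\n".join(fasta) + "\n")
        put("transcripts.tsv",
            "#transcript_id\tgene_id\tfamily_id\tspecies\tchromosome\t"
            "start\tend\tis_tree_transcript\n" + "\n".join(meta) + "\n")
        put("clan_map.tsv",
            "".join(f"{d}\t{c}\n" for d, c in sorted(self.clan_map.items())))
        put("disorder.tsv", "".join(
            f"{sid}\t{score:.3f}\n"
            for sid, track in sorted(self.tracks.items())
            for score in track.scores
        ))
        put("segdups.bedpe", "".join(
            f"{p.chrom1}\t{p.start1}\t{p.end1}\t{p.chrom2}\t{p.start2}\t"
            f"{p.end2}\n" for p in self.segdups
        ))
        put("truth.json", json.dumps(
            [
                {
                    "family_id": e.family_id,
                    "gain_node": e.gain_node,
                    "character_id": e.character_id,
                    "mechanism": e.mechanism,
                    "donor_gene_id": e.donor_gene_id,
                    "position": e.structure.position,
                    "exon_category": e.structure.exon_category,
                    "n_new_exons": e.structure.n_new_exons,
                    "symmetric_phase_flag": e.structure.symmetric_phase_flag,
                    "age_group": e.age_group,
                    "donor_same_chromosome": e.donor_same_chromosome,
                    "lost_leaves": list(e.lost_leaves),
                }
                for e in self.truth
            ],
            indent=1,
        ))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length, p=_AA_FREQ))


def _mutate(rng: np.random.Generator, seq: str, p: float) -> str:
    if p <= 0:
        return seq
    chars = np.array(list(seq))
    mask = rng.random(len(chars)) < p
    if mask.any():
        chars[mask] = rng.choice(AMINO_ACIDS, size=int(mask.sum()), p=_AA_FREQ)
    return "".join(chars)


@dataclass
class _FamilyPlan:
    """Everything one family needs, resolved before sequences are built."""

    family_id: str
    mechanism: str
    age_group: str
    gain_species: list[str]
    outgroup_species: list[str]


def _build_tree(
    rng: np.random.Generator, plan: _FamilyPlan, dup_p: float
) -> tuple[GeneTree, str, list[str]]:
    """Caterpillar spine of outgroups over a gain clade.

    The gain node sits at depth >= 3, so isolating its subtree by losses
    would cost at least three loss events (> one gain at cost 2) and
    weighted parsimony recovers the planted gain exactly in the loss-free
    regime.
    Returns (tree, gain node name, gain clade gene ids).
    """
    fam = plan.family_id
    counter = [0]

    def leaf(species: str) -> TreeNode:
        counter[0] += 1
        return TreeNode(
            name=f"{fam}_g{counter[0]}",
            branch_length=float(rng.uniform(0.05, 0.5)),
            node_kind="leaf",
            species=species,
        )

    def internal(children: list[TreeNode], name: str) -> TreeNode:
        return TreeNode(
            name=name,
            children=children,
            branch_length=float(rng.uniform(0.05, 0.5)),
            node_kind=(
                "duplication" if rng.random() < dup_p else "speciation"
            ),
        )

    # gain clade: random (caterpillar) shape over the gain species
    nodes = [leaf(s) for s in plan.gain_species]
    inner = 0
    while len(nodes) > 1:
        inner += 1
        right = nodes.pop()
        left = nodes.pop()
        nodes.append(internal([left, right], f"{fam}_gain{inner}"))
    gain_clade = nodes[0]
    gain_node_name = gain_clade.name
    gain_genes = [l.name for l in gain_clade.leaves()]

    node = gain_clade
    for i, species in enumerate(plan.outgroup_species):
        node = internal([leaf(species), node], f"{fam}_n{i}")
    node.branch_length = 0.0
    return GeneTree(node), gain_node_name, gain_genes


def _insert_exon_block(
    model: ExonModel,
    at_junction: int,
    lengths: Sequence[int],
    upstream_phase: int,
    internal_phases: Sequence[int],
    downstream_phase: int,
) -> tuple[ExonModel, int]:
    """Insert new exons at an internal junction of an exon model.

    Returns the new model and the protein coordinate where the block starts.
    ``at_junction`` is the index of the junction (between exon i and i+1).
    """
    exons = list(model.exons)
    phases = list(model.phases)
    insert_at = exons[at_junction][1]
    block_len = sum(lengths)
    new_exons = []
    pos = insert_at
    for ln in lengths:
        new_exons.append((pos, pos + ln))
        pos += ln
    shifted = [(s + block_len, e + block_len) for s, e in exons[at_junction + 1:]]
    out_exons = exons[: at_junction + 1] + new_exons + shifted
    out_phases = (
        phases[:at_junction]
        + [upstream_phase]
        + list(internal_phases)
        + [downstream_phase]
        + phases[at_junction + 1:]
    )
    return ExonModel(tuple(out_exons), tuple(out_phases)), insert_at


def simulate_family(
    rng: np.random.Generator,
    plan: _FamilyPlan,
    cfg: SimulationConfig,
    anc_domain_id: str,
    gained_domain_block: str,
    chrom_of: dict[str, str],
    span_of: dict[str, tuple[int, int]],
) -> tuple[GeneFamily, PlantedEvent, list[ProteomeEntry], list[SegDupPair]]:
    """Build one family with its planted gain; returns extra proteome
    entries (donor genes) and any segmental-duplication support pairs."""
    fam = plan.family_id
    tree, gain_node, gain_genes = _build_tree(
        rng, plan, cfg.duplication_probability
    )

    # ancestral architecture --------------------------------------------
    exon_lengths = cfg.ancestral_exon_lengths
    anc_len = sum(exon_lengths)
    anc_seq = _random_sequence(rng, anc_len)
    bounds = np.cumsum((0,) + tuple(exon_lengths))
    anc_exons = tuple(
        (int(bounds[i]), int(bounds[i + 1])) for i in range(len(exon_lengths))
    )
    anc_phases = tuple(int(p) for p in rng.integers(0, 3, len(exon_lengths) - 1))
    anc_model = ExonModel(anc_exons, anc_phases)
    # the ancestral domain sits wholly inside exon 2, clear of the junction
    # used for middle insertions, so planted gains never split it
    anc_dom_start = int(anc_exons[1][0] + 3)
    anc_dom_end = int(anc_exons[1][1] - 3)

    # planted insertion --------------------------------------------------
    L = cfg.domain_length
    block = gained_domain_block
    mech = plan.mechanism
    donor_entries: list[ProteomeEntry] = []
    segdups: list[SegDupPair] = []
    donor_gene_id: str | None = None
    donor_same_chrom: bool | None = None

    # choose host junction for middle insertions: between exons 2 and 3
    junction = 1

    if mech == RETROPOSITION:
        up = int(anc_phases[junction])
        down = (up + 1) % 3  # asymmetric on purpose
        gained_model, insert_at = _insert_exon_block(
            anc_model, junction, [L], up, [], down
        )
        planted = StructureCall(
            position=MIDDLE, exon_category=SINGLE_NEW, n_new_exons=1,
            flanking_phases=(up, down), symmetric_phase_flag=False,
        )
        donor_gene_id = f"{fam}_donor"
        donor_same_chrom = False
    elif mech == ADJACENT_JOINING:
        side = AMINO if rng.random() < 0.5 else CARBOXY
        half = L // 2
        if side == CARBOXY:
            exons = anc_model.exons + (
                (anc_len, anc_len + half), (anc_len + half, anc_len + L),
            )
            phases = anc_model.phases + (
                int(rng.integers(0, 3)), int(rng.integers(0, 3)),
            )
            gained_model, insert_at = ExonModel(exons, phases), anc_len
        else:
            exons = ((0, half), (half, L)) + tuple(
                (s + L, e + L) for s, e in anc_model.exons
            )
            phases = (
                int(rng.integers(0, 3)), int(rng.integers(0, 3)),
            ) + anc_model.phases
            gained_model, insert_at = ExonModel(exons, phases), 0
        planted = StructureCall(
            position=side, exon_category=MULTIPLE_NEW, n_new_exons=2,
        )
        donor_gene_id = f"{fam}_donor"
        donor_same_chrom = True
    elif mech == INTRONIC_INSERTION:
        p = int(anc_phases[junction])  # intron insertion keeps the phase
        half = L // 2
        gained_model, insert_at = _insert_exon_block(
            anc_model, junction, [half, L - half], p,
            [int(rng.integers(0, 3))], p,
        )
        planted = StructureCall(
            position=MIDDLE, exon_category=MULTIPLE_NEW, n_new_exons=2,
            flanking_phases=(p, p), symmetric_phase_flag=True,
        )
    elif mech == EXONIZATION:
        exons = anc_model.exons[:-1] + (
            (anc_model.exons[-1][0], anc_len + L),
        )
        gained_model, insert_at = ExonModel(exons, anc_model.phases), anc_len
        planted = StructureCall(
            position=CARBOXY, exon_category=EXTENSION_ONLY, n_new_exons=0,
        )
    else:  # pragma: no cover - config validation prevents this
        raise ValueError(f"unknown mechanism {mech!r}")

    gained_span = (insert_at, insert_at + L)
    gained_domain_id = f"PF9{fam.split('f')[-1].zfill(4)}"

    # losses below the gain node ----------------------------------------
    lost: set[str] = set()
    if cfg.loss_probability > 0:
        for g in gain_genes[1:]:  # keep at least the first gain leaf
            if rng.random() < cfg.loss_probability:
                lost.add(g)

    # sequences per leaf --------------------------------------------------
    transcripts: dict[str, list[Transcript]] = {}
    hits: list[DomainHit] = []
    genome_rng = rng
    chroms = [f"chr{i}" for i in range(1, 11)]

    def place_gene(gene_id: str, preferred_chrom: str | None = None,
                   near: tuple[str, int] | None = None) -> None:
        if near is not None:
            chrom_of[gene_id] = near[0]
            start = near[1]
        else:
            chrom_of[gene_id] = preferred_chrom or str(
                genome_rng.choice(chroms)
            )
            start = int(genome_rng.integers(1_000, 5_000_000))
        span_of[gene_id] = (start, start + 10_000)

    # evolve the ancestral sequence (and the gained block below the gain
    # node) along the tree: substitutions accumulate per branch
    leaf_base: dict[str, str] = {}
    leaf_block: dict[str, str] = {}

    def evolve(node: TreeNode, base: str, blk: str | None) -> None:
        base = _mutate(rng, base, cfg.substitution_probability)
        if blk is not None:
            blk = _mutate(rng, blk, cfg.substitution_probability)
        if node.name == gain_node:
            blk = block
        if node.is_leaf:
            leaf_base[node.name] = base
            if blk is not None:
                leaf_block[node.name] = blk
            return
        for child in node.children:
            evolve(child, base, blk)

    for child in tree.root.children:
        evolve(child, anc_seq, None)

    for leaf_node in tree.leaves():
        gene = leaf_node.name
        tid = f"{gene}_t1"
        has_gain = gene in gain_genes and gene not in lost
        base = leaf_base[gene]
        if has_gain:
            seg = leaf_block.get(gene, block)
            seq = base[:insert_at] + seg + base[insert_at:]
            model = gained_model
        else:
            seq, model = base, anc_model
        place_gene(gene)
        transcripts[gene] = [
            Transcript(
                transcript_id=tid,
                gene_id=gene,
                species=leaf_node.species,
                protein_sequence=seq,
                exon_model=model,
                chromosome=chrom_of[gene],
                genomic_span=span_of[gene],
            )
        ]
        # ancestral domain hit on every transcript
        if has_gain and insert_at <= anc_dom_start:
            a_start, a_end = anc_dom_start + L, anc_dom_end + L
        else:
            a_start, a_end = anc_dom_start, anc_dom_end
        hits.append(
            DomainHit(tid, anc_domain_id, a_start, a_end,
                      e_value=1e-30, model_coverage=0.9)
        )
        if has_gain:
            hits.append(
                DomainHit(tid, gained_domain_id, gained_span[0],
                          gained_span[1], e_value=1e-25, model_coverage=0.95)
            )

    family = GeneFamily(
        family_id=fam, tree=tree, transcripts=transcripts, hits=hits
    )

    # donor gene ----------------------------------------------------------
    human_gene = next(
        g for g in gain_genes
        if transcripts[g][0].species == "human"
    )
    if donor_gene_id is not None:
        flank1 = _random_sequence(rng, 30)
        flank2 = _random_sequence(rng, 30)
        donor_seq = flank1 + block + flank2
        donor_tid = f"{donor_gene_id}_t1"
        if donor_same_chrom:
            rec_chrom = chrom_of[human_gene]
            rec_span = span_of[human_gene]
            place_gene(donor_gene_id, near=(rec_chrom, rec_span[1] + 2_000))
        else:
            rec_chrom = chrom_of[human_gene]
            others = [c for c in chroms if c != rec_chrom]
            place_gene(donor_gene_id,
                       preferred_chrom=str(genome_rng.choice(others)))
        donor_entries.append(
            ProteomeEntry(
                protein_id=donor_tid,
                gene_id=donor_gene_id,
                sequence=donor_seq,
                chromosome=chrom_of[donor_gene_id],
                genomic_span=span_of[donor_gene_id],
            )
        )
        if mech == ADJACENT_JOINING and rng.random() < cfg.segdup_fraction:
            rs, re_ = span_of[human_gene]
            ds, de = span_of[donor_gene_id]
            segdups.append(
                SegDupPair(chrom_of[human_gene], rs + 100, rs + 600,
                           chrom_of[donor_gene_id], ds + 100, ds + 600)
            )

    event = PlantedEvent(
        family_id=fam,
        gain_node=gain_node,
        character_id=gained_domain_id,
        mechanism=mech,
        donor_gene_id=donor_gene_id,
        structure=planted,
        age_group=plan.age_group,
        donor_same_chromosome=donor_same_chrom,
        lost_leaves=tuple(sorted(lost)),
    )
    return family, event, donor_entries, segdups


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset of families with planted, labelled gains."""
    rng = np.random.default_rng(cfg.seed)

    # shared inventory of ancestral domain identifiers (clan-mapped in part)
    inventory = [f"PF{10000 + i}" for i in range(cfg.domain_inventory_size)]
    clan_map = {
        dom: f"CL{5000 + i // 2}" for i, dom in enumerate(inventory[: len(inventory) // 2])
    }

    mech_counts = np.floor(
        np.asarray(cfg.mechanism_mix) * cfg.n_families
    ).astype(int)
    while mech_counts.sum() < cfg.n_families:
        mech_counts[int(np.argmax(np.asarray(cfg.mechanism_mix)))] += 1
    mech_list = [
        m for m, n in zip(MECHANISMS_IN_MIX, mech_counts) for _ in range(n)
    ]
    rng.shuffle(mech_list)

    age_names = [name for name, _ in DEFAULT_CLADE_MAP]
    families: list[GeneFamily] = []
    proteome: list[ProteomeEntry] = []
    truth: list[PlantedEvent] = []
    segdups: list[SegDupPair] = []
    tracks: dict[str, DisorderTrack] = {}
    chrom_of: dict[str, str] = {}
    span_of: dict[str, tuple[int, int]] = {}

    for i, mech in enumerate(mech_list):
        fam_id = f"f{i:04d}"
        age = age_names[int(rng.integers(0, len(age_names)))]
        n_gain = int(rng.integers(cfg.gain_clade_leaves[0],
                                  cfg.gain_clade_leaves[1] + 1))
        pool = _GAIN_CLADE_POOLS[age]
        gain_species = ["human"] + [
            str(rng.choice(pool)) for _ in range(n_gain - 1)
        ]
        n_out = int(rng.integers(cfg.n_outgroups[0], cfg.n_outgroups[1] + 1))
        outgroups = [str(rng.choice(_OUTGROUP_SPECIES)) for _ in range(n_out)]
        plan = _FamilyPlan(fam_id, mech, age, gain_species, outgroups)
        anc_dom = inventory[int(rng.integers(0, len(inventory)))]
        block = _random_sequence(rng, cfg.domain_length)
        family, event, donors, fam_segdups = simulate_family(
            rng, plan, cfg, anc_dom, block, chrom_of, span_of
        )
        families.append(family)
        truth.append(event)
        proteome.extend(donors)
        segdups.extend(fam_segdups)

    # family transcripts join the searchable proteome
    for fam in families:
        for t in fam.all_transcripts():
            proteome.append(
                ProteomeEntry(
                    protein_id=t.transcript_id,
                    gene_id=t.gene_id,
                    sequence=t.protein_sequence,
                    chromosome=t.chromosome,
                    genomic_span=t.genomic_span,
                )
            )

    # disorder tracks: high inside exonized gained segments, low elsewhere
    exonized_spans: dict[str, tuple[int, int]] = {}
    for fam, event in zip(families, truth):
        if event.mechanism != EXONIZATION:
            continue
        for h in fam.hits:
            if h.domain_id == event.character_id:
                exonized_spans[h.sequence_id] = (h.start, h.end)
    for fam in families:
        for t in fam.all_transcripts():
            n = len(t.protein_sequence)
            scores = np.clip(
                rng.normal(cfg.disorder_mean_background, 0.05, n), 0.0, 1.0
            )
            span = exonized_spans.get(t.transcript_id)
            if span is not None:
                scores[span[0]:span[1]] = np.clip(
                    rng.normal(cfg.disorder_mean_exonized,
                               0.05, span[1] - span[0]),
                    0.0, 1.0,
                )
            tracks[t.transcript_id] = DisorderTrack(
                t.transcript_id, tuple(float(s) for s in scores)
            )

    return SimulatedDataset(
        families=families,
        proteome=proteome,
        tracks=tracks,
        segdups=segdups,
        clan_map=clan_map,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


@dataclass
class RecoveryTable:
    """Recovery of planted events by the pipeline, per mechanism."""

    per_mechanism: dict[str, dict[str, int]]
    gain_node_recall: float
    structure_recovery: float
    mechanism_recovery: float
    precision: float | None
    n_planted: int
    n_called: int

    def as_dict(self) -> dict:
        return {
            "per_mechanism": self.per_mechanism,
            "gain_node_recall": self.gain_node_recall,
            "structure_recovery": self.structure_recovery,
            "mechanism_recovery": self.mechanism_recovery,
            "precision": self.precision,
            "n_planted": self.n_planted,
            "n_called": self.n_called,
        }


def evaluate_recovery(truth: Sequence[PlantedEvent], classified) -> RecoveryTable:
    """Compare pipeline calls against the planted ground truth.

    ``classified`` is a sequence of
    :class:`~domgain.mechanism_donor.ClassifiedEvent`.  Gain-node recall is
    the fraction of planted events whose (family, node, character) was
    called; structure and mechanism recovery are conditional on the gain
    node being recovered.
    """
    truth_fams = {e.family_id for e in truth}
    called_fams = {ce.event.family_id for ce in classified}
    stray = called_fams - truth_fams
    if stray:
        raise ValueError(f"calls reference unknown families: {sorted(stray)}")

    by_key = {
        (ce.event.family_id, ce.event.node_name): ce for ce in classified
    }
    per_mech: dict[str, dict[str, int]] = {}
    n_node = n_struct = n_mech = 0
    for ev in truth:
        row = per_mech.setdefault(
            ev.mechanism,
            {"planted": 0, "node_recovered": 0, "structure_recovered": 0,
             "mechanism_recovered": 0},
        )
        row["planted"] += 1
        ce = by_key.get((ev.family_id, ev.gain_node))
        if ce is None or ev.character_id not in ce.event.character_ids:
            continue
        row["node_recovered"] += 1
        n_node += 1
        s_ok = (
            ce.structure.position == ev.structure.position
            and ce.structure.exon_category == ev.structure.exon_category
        )
        if s_ok:
            row["structure_recovered"] += 1
            n_struct += 1
        if ce.mechanism.label == ev.mechanism:
            row["mechanism_recovered"] += 1
            n_mech += 1

    n_planted = len(truth)
    n_called = len(classified)
    true_keys = {(e.family_id, e.gain_node) for e in truth}
    n_true_called = sum(
        1 for ce in classified
        if (ce.event.family_id, ce.event.node_name) in true_keys
    )
    return RecoveryTable(
        per_mechanism=per_mech,
        gain_node_recall=n_node / n_planted if n_planted else 0.0,
        structure_recovery=n_struct / n_node if n_node else 0.0,
        mechanism_recovery=n_mech / n_node if n_node else 0.0,
        precision=n_true_called / n_called if n_called else None,
        n_planted=n_planted,
        n_called=n_called,
    )
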