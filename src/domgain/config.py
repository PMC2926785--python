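"""Configuration objects: numeric cutoffs, alignment scoring, clade maps.

Every threshold the pipeline applies is collected in :class:`ThresholdConfig`
so that a run is fully described by one object.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class RescueTier:
    """One disjunct of the domain-rescue rule.

    A missing domain is added to a family member when a local alignment
    against a family instance of the domain satisfies *any* tier:
    E-value strictly below ``max_evalue`` and at least ``min_fraction``
    of the domain sequence aligned.
    """

    max_evalue: float
    min_fraction: float

    def passes(self, evalue: float, fraction: float) -> bool:
        return evalue < self.max_evalue and fraction >= self.min_fraction


@dataclass
class ThresholdConfig:
    """All numeric cutoffs of the gain-calling and classification funnel.

    Attributes
    ----------
    gain_cost, loss_cost
        Weighted-parsimony edge costs for a 0->1 gain and a 1->0 loss.
        Gains must be strictly more expensive than losses.
    fragment_evalue, fragment_model_coverage
        A domain hit present on a single family sequence is discarded as a
        fragmentary false positive iff its E-value exceeds ``fragment_evalue``
        AND it covers at most ``fragment_model_coverage`` of the domain model.
    rescue_tiers
        Disjunctive significance tiers for adding missed domains
        (E < 1e-4 with >= 60% of the domain present, or E < 1e-7 with
        >= 40%, or E < 1e-10 with any length).
    exclusion_identity
        A gain event is discarded when the gained-domain sequence shares at
        least this fraction of identical aligned residues (relative to the
        domain length) with any family sequence lacking the domain.
    boundary_identity, boundary_min_len
        Exon-extension call: the first/last third of the exon sequence
        outside the gained domain must be at least ``boundary_min_len``
        residues and share >= ``boundary_identity`` identity with a
        domain-lacking homolog.
    novel_exon_novel_fraction, novel_exon_max_identity,
    short_exon_len, short_exon_max_identity
        Exon-novelty call: an exon is novel iff >= 85% of its residues are
        unaligned to every homolog, or its best identity to any homolog is
        < 10% (< 40% for exons of <= 20 residues).
    donor_evalue, donor_coverage
        Donor-gene search: a proteome hit is significant iff E < 1e-4 and
        at least 60% of the gained-domain sequence is aligned.
    disorder_cutoff
        A residue counts as disordered when its per-residue disorder score
        is >= this value (the usual IUPred convention).
    """

    gain_cost: float = 2.0
    loss_cost: float = 1.0
    fragment_evalue: float = 1e-6
    fragment_model_coverage: float = 0.30
    rescue_tiers: tuple[RescueTier, ...] = (
        RescueTier(1e-4, 0.60),
        RescueTier(1e-7, 0.40),
        RescueTier(1e-10, 0.0),
    )
    exclusion_identity: float = 0.16
    boundary_identity: float = 0.30
    boundary_min_len: int = 7
    novel_exon_novel_fraction: float = 0.85
    novel_exon_max_identity: float = 0.10
    short_exon_len: int = 20
    short_exon_max_identity: float = 0.40
    donor_evalue: float = 1e-4
    donor_coverage: float = 0.60
    disorder_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not self.gain_cost > self.loss_cost > 0:
            raise ValueError("require gain_cost > loss_cost > 0")
        for name in (
            "fragment_model_coverage",
            "exclusion_identity",
            "boundary_identity",
            "novel_exon_novel_fraction",
            "novel_exon_max_identity",
            "short_exon_max_identity",
            "donor_coverage",
            "disorder_cutoff",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class ScoringConfig:
    """Protein local-alignment scoring and significance parameters.

    BLOSUM62 with affine gaps (open 11, extend 1) — the standard protein
    blast regime.  Significance is a Karlin–Altschul E-value
    ``E = K * m * n * exp(-lambda * S)`` with published gapped BLOSUM62
    constants; ``n`` is the total number of target residues scanned by the
    enclosing operation.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041


#: Species tags used by the bundled clade map (NHX ``S=`` values).
QUALITY_SPECIES: frozenset[str] = frozenset(
    {
        "human",
        "mouse",
        "rat",
        "chicken",
        "zebrafish",
        "frog",
        "fruit_fly",
    }
)

#: Nested evolutionary groups, youngest first.  The age group of a gain
#: event is the smallest group containing every descendant species.
DEFAULT_CLADE_MAP: tuple[tuple[str, frozenset[str]], ...] = (
    ("primates", frozenset({"human", "chimp", "macaque"})),
    (
        "mammals",
        frozenset(
            {"human", "chimp", "macaque", "mouse", "rat", "dog", "cow", "opossum"}
        ),
    ),
    (
        "vertebrates",
        frozenset(
            {
                "human",
                "chimp",
                "macaque",
                "mouse",
                "rat",
                "dog",
                "cow",
                "opossum",
                "chicken",
                "frog",
                "zebrafish",
                "fugu",
            }
        ),
    ),
    (
        "bilateria",
        frozenset(
            {
                "human",
                "chimp",
                "macaque",
                "mouse",
                "rat",
                "dog",
                "cow",
                "opossum",
                "chicken",
                "frog",
                "zebrafish",
                "fugu",
                "fruit_fly",
                "mosquito",
                "worm",
            }
        ),
    ),
    (
        "animals",
        frozenset(
            {
                "human",
                "chimp",
                "macaque",
                "mouse",
                "rat",
                "dog",
                "cow",
                "opossum",
                "chicken",
                "frog",
                "zebrafish",
                "fugu",
                "fruit_fly",
                "mosquito",
                "worm",
                "sea_anemone",
                "sponge",
            }
        ),
    ),
)

AGE_GROUPS: tuple[str, ...] = tuple(name for name, _ in DEFAULT_CLADE_MAP)
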