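# Methods

## Model and procedure

The pipeline treats each protein-domain family (or clan) as a binary
character on a rooted, duplication/speciation-labelled gene-family tree.
A gene *has* the character when any of its splice variants carries a hit
for it; presence is blind to whether the hit came from the original HMM
scan or from the rescue step.

**Weighted parsimony.** Ancestral states are reconstructed by Sankoff
parsimony with asymmetric edge costs: a gain (0→1) costs 2, a loss (1→0)
costs 1, and both root states carry zero prior cost. Branch lengths do not
enter the objective — costs are per event, not per unit length; lengths are
used only by the enrichment statistic. Because a gain is twice as expensive
as a loss, patchy presence is preferentially explained by ancestral
presence plus losses, which makes surviving gain calls conservative. Among
minimum-cost labellings, ties are broken toward fewer gains (a labelling
without a gain beats a tying labelling with one), then fewer total events,
then absence; the dynamic program carries the lexicographic triple
(cost, gains, events) per node and state, which is exact because the
objective decomposes over independent child subtrees.

One stated property of this scheme deserves a caveat: it is *not* true in
general that a minimum-cost labelling never places a gain and a loss on one
root-to-leaf path. A loss high on a long spine followed by a deeper regain
(cost 3) can strictly beat four or more independent losses; such trees need
≥ 7 leaves. The tie rule only guarantees that a gain is never reported when
a gain-free labelling achieves the same cost. The test-suite checks the
cost optimum against exhaustive enumeration instead of asserting the
per-path claim.

**The funnel.** Gains survive, in order: (1) Dollo concordance — all gains
of a character in a family are discarded unless exactly one gain of it is
reported; (2) leaf-gain exclusion — a gain subtended by a single sequence
is likely an annotation artifact; (3) representative selection — a
descendant transcript that is its gene's tree transcript, carries a direct
(non-rescued) hit, and belongs to a quality-genome species (fruit fly,
frog, zebrafish, chicken, mouse, rat, human; human preferred, remaining
ties broken lexicographically); (4) a similarity screen — the event is
dropped when the gained-domain sequence shares ≥ 16% identical aligned
residues (relative to the domain length) with any family sequence lacking
the domain; (5) grouping — characters gained at the same node merge into
one event; (6) an optional user-supplied blacklist of (family, node) pairs,
standing in for case-by-case manual exclusions. Each stage's output is a
subset of its input, and the per-stage counts are reported as a funnel.

**Alignment and identities.** All alignments are BLOSUM62 with affine gaps
(open 11, extend 1, applied as 11 for the first gap position and 1 for each
extension). Local (Smith–Waterman) alignments drive the rescue and donor
searches; their significance is a Karlin–Altschul E-value
`E = K·m·n·exp(−λS)` with the published gapped BLOSUM62 constants
(λ = 0.267, K = 0.041), where `n` is the total number of target residues
scanned by the operation. The constants and matrix are configurable
(`ScoringConfig`).

The *identity* quantities used by the similarity screen and the structural
rules are read instead from a full-length pairwise alignment of the
representative protein against each domain-lacking homolog, computed
globally with free end gaps. This is the pairwise analogue of reading a
family multiple alignment column-wise: the shared ancestral sequence
anchors the alignment, so residues of a genuinely novel insertion fall in
gap columns. Identities are counted as identical aligned residues divided
by the length of the region under test (the gained domain, an exon, or a
boundary third). Per-aligned-column identity of an optimal local alignment
was rejected for these rules: between unrelated sequences it concentrates
on short chance segments at 40–60% identity, which would make the 10% and
16% cutoffs meaningless, and in a forced overlap alignment of an exon alone
nearly every residue is "aligned", which would make the 85%-unaligned
clause vacuous.

**Structure rules.** An exon is novel iff ≥ 85% of its residues are
unaligned against every homolog, or its best identity to any homolog is
< 10% (< 40% for exons of ≤ 20 residues — short exons cannot demonstrate
high unaligned fractions reliably). An exon partially overlapped by the
gained domain is an extension of an ancestral exon iff the first/last third
of its sequence outside the domain (rounded down, minimum 7) is ≥ 7
residues long and ≥ 30% identical to some homolog; regions shorter than 7
residues are not tested. The known consequence that extensions are
over-called by this permissive rule is preserved deliberately — no extra
stringency is added. Position: a domain overlapping the first (last) coding
exon is amino- (carboxy-)terminal; otherwise the maximal contiguous run of
novel exons containing the domain's novel exons is examined, and the gain
is still terminal when that run reaches a terminus (every exon between the
domain and the terminus was gained with it); everything else is middle.
The exon category follows from the size of that novel run and the
extension flags; zero novel exons with no extension is recorded as
ambiguous, and the event is retained with that flag. Phase symmetry is
defined only for middle gains with introns on both sides of the novel
block and is true iff the two flanking phases are equal.

**Mechanism rules**, in precedence order: terminal gain with ≥ 2 novel
exons → adjacent-gene joining (this outranks retroposition because a
terminal multi-exon signature admits only one plausible mechanism, and
several single-exon candidates are better explained by joining); single
novel exon with a donor found → retroposition candidate; middle novel
exon(s) with symmetric flanking phases → intronic insertion; extension
only → exonization candidate; otherwise unclassified. The labels are
recorded hypotheses, each with the rule that fired. A domain coded by
multiple exons can never be labelled retroposition — intron presence rules
it out — and this holds by construction of the rule order.

**Donor search.** The gained-domain sequence is aligned against every
proteome entry outside the recipient's paralog set (same-family genes plus
any user-supplied list). A hit qualifies iff E < 1e-4 and ≥ 60% of the
domain sequence is aligned; the best hit wins, ties broken by lower
E-value then lexicographic protein id. An exact 4-mer prefilter skips
targets sharing no word with the query (blast-like seeding, purely a
performance device; the E-value search space remains the full proteome).
Segmental-duplication support is flagged when one side of a BEDPE pair
overlaps (≥ 1 base, half-open) the recipient gene and the mate overlaps
the donor or one of its paralogs.

**Statistics.** The terminal-enrichment test is a one-degree-of-freedom
chi-square goodness of fit, computed explicitly as Σ(O−E)²/E with the
p-value from the chi-square survival function; expected cell counts below
5 raise a warning. Expected proportions default to the terminal/middle
split of all domain instances in the input families and may be overridden.
Duplication-vs-speciation enrichment compares the observed ratio of gains
after duplication nodes vs speciation nodes against two expectations: the
summed child-branch lengths of duplication vs speciation nodes, and their
node counts. Disorder summaries call a residue disordered at score ≥ 0.5
(the usual convention for disorder predictors; the cutoff is configurable
because no single published value governs it) and report the mean
disordered fraction of gained domains per exon category plus the pooled
mean over all other domains on the same representative proteins.
Human-readable percentages round half-up to integers; JSON output keeps
full precision.

## The synthetic generator

`simulate_dataset` emulates the statistical structure the analysis
assumes: one planted gain per family, rarer losses, and mechanism-specific
exon signatures. Each family is a caterpillar spine of 3–5 outgroup leaves
over a 2–4 leaf gain clade (always including human, so a quality
representative exists); the gain node therefore sits at depth ≥ 3, where a
single gain (cost 2) strictly beats the ≥ 3 losses needed to explain the
pattern by ancestral presence, so parsimony recovers the planted node
exactly in the loss-free regime. Internal nodes are labelled duplications
with probability 0.3; branch lengths are uniform on [0.05, 0.5].

The ancestral protein has four exons (40/50/45/40 aa) with random phases
and one ancestral domain wholly inside exon 2. Gained domains are 80-aa
blocks — a typical domain size — of high-entropy sequence drawn from
natural amino-acid background frequencies (Robinson–Robinson), the
composition the aligner's significance constants assume, so chance
alignment scores behave like real proteins. Mechanism constructions:
retroposition inserts one novel exon exactly covering the domain between
exons 2 and 3 with deliberately unequal flanking phases and plants a
multi-exon donor gene on a different chromosome; adjacent-gene joining
appends two novel exons at a random terminus and plants a donor adjacent
on the recipient's chromosome (a BEDPE segmental-duplication pair supports
half of these events by default); intronic insertion places two novel
exons in the intron between exons 2 and 3 with both flanking phases equal
to the ancestral phase (a true intron insertion preserves the phase on
both sides); exonization extends the last exon with the domain, plants no
donor, and raises the disorder scores of the gained segment (mean 0.8 vs
background 0.1, σ = 0.05, clipped to [0, 1]). Substitutions accumulate
per branch at a configurable per-site rate; losses apply per gain-clade
leaf (the human leaf is spared so a representative survives). Everything
derives from one seeded generator; identical seeds give byte-identical
output files.

What the generator does *not* emulate: indels and codon-level evolution,
alternative splicing (one transcript per gene by default), misannotation,
domain duplications within a protein, and realistic genome geography
beyond a toy 10-chromosome layout. Passing tests therefore demonstrate
that the decision rules fire correctly on their intended signatures and
that the funnel's logic is sound — not that real gene-family and
domain-annotation databases would yield the same recovery rates.

## Problem sizes and numerical choices

The recovery benchmark runs 200 families with mechanism mix
(0.1, 0.5, 0.2, 0.2), no losses and no substitution noise; the parsimony
oracle check enumerates all internal labellings on 1,000 random trees of
2–8 leaves. These sizes exercise every rule while keeping a full run in
the low minutes on one CPU. All coordinates are 0-based half-open
internally; 1-based inclusive appears only at GFF3 and hit-table
boundaries. A missing NHX `D` tag means speciation (the conservative
reading: fewer duplication-associated gains). Degenerate inputs are
defined, not errors: a character absent from all leaves yields no events;
a family with no domain-lacking sequences passes the similarity screen
vacuously; a terminal novel block has undefined phase symmetry, recorded
as not-applicable.

## Known limitations

* The rescue and donor E-values are analytic Karlin–Altschul estimates,
  not empirical blast E-values; at the published thresholds (1e-4) chance
  rescues are expected roughly once per ~10⁴ comparisons, and very large
  simulated datasets will occasionally show one — visible as a single
  missed gain when an outgroup is falsely rescued.
* The 16% screen aligns the representative full-length against each
  domain-lacking family sequence; trimmed-region alignment is not
  implemented.
* Exon extensions are over-called by design (7-aa boundary evidence
  suffices), matching the permissive published rule.
* Mechanism labels are rule-based hypotheses; no repeat-element,
  synteny-break or pseudogene-signature evidence is consulted.
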