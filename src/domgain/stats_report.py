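"""Summary statistics and report tables for classified gain events.

Covers the pipeline's headline summaries: the position x exon-category
distribution of gains, the chi-square test for terminal enrichment, the
duplication-vs-speciation enrichment of gains (under branch-length and
node-count expectations), per-category intrinsic-disorder fractions, and
the filtering-funnel report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from .config import ThresholdConfig
from .io_model import DUPLICATION, DisorderTrack, GeneFamily
from .gain_inference import FUNNEL_STAGES, GainEvent
from .mechanism_donor import ClassifiedEvent
from .structure_classification import AMBIGUOUS, CATEGORIES, POSITIONS


def round_half_up_percent(x: float) -> int:
    """Percentage rounding used in human-readable reports (half-up)."""
    return int(Decimal(x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int) -> float:
    return 100.0 * numerator / denominator if denominator else 0.0


# ---------------------------------------------------------------------------
# position x category distribution
# ---------------------------------------------------------------------------


def summarize_distribution(
    classified: Sequence[ClassifiedEvent],
) -> pd.DataFrame:
    """Counts and percentages of events per (position, exon category).

    Percentages are of the total event count, full precision in the frame;
    reports round half-up.  Empty input yields an empty (all-zero counts)
    frame rather than an error.
    """
    rows = []
    total = len(classified)
    counts: dict[tuple[str, str], int] = {}
    for ce in classified:
        key = (ce.structure.position, ce.structure.exon_category)
        counts[key] = counts.get(key, 0) + 1
    for position in POSITIONS:
        for category in CATEGORIES:
            n = counts.get((position, category), 0)
            rows.append(
                {
                    "position": position,
                    "exon_category": category,
                    "count": n,
                    "percent": percent(n, total),
                }
            )
    frame = pd.DataFrame(rows)
    return frame[frame["count"] > 0].reset_index(drop=True) if total else frame.iloc[0:0]


def position_shares(classified: Sequence[ClassifiedEvent]) -> dict[str, float]:
    """Percent of events per position (of all events, full precision)."""
    total = len(classified)
    out: dict[str, float] = {}
    for pos in POSITIONS:
        n = sum(1 for ce in classified if ce.structure.position == pos)
        out[pos] = percent(n, total)
    return out


# ---------------------------------------------------------------------------
# chi-square terminal enrichment
# ---------------------------------------------------------------------------


@dataclass
class ChiSquareResult:
    statistic: float
    p_value: float
    dof: int
    warning: str | None = None


def terminal_enrichment_test(
    observed: Sequence[int],
    expected_proportions: Sequence[float],
) -> ChiSquareResult:
    """One-sample goodness-of-fit chi-square for terminal vs middle counts.

    ``observed`` are counts (terminal, middle); ``expected_proportions``
    the null shares.  The statistic is computed explicitly as
    ``sum((O - E)^2 / E)``; the p-value from the chi-square survival
    function with ``len(observed) - 1`` degrees of freedom.
    """
    if len(observed) != len(expected_proportions):
        raise ValueError("observed and expected must have equal length")
    n = sum(observed)
    expected = [p * n for p in expected_proportions]
    if any(e == 0 and o > 0 for e, o in zip(expected, observed)):
        return ChiSquareResult(
            statistic=math.nan, p_value=math.nan,
            dof=len(observed) - 1,
            warning="expected count of zero with nonzero observed: undefined",
        )
    statistic = sum(
        (o - e) ** 2 / e for o, e in zip(observed, expected) if e > 0
    )
    dof = len(observed) - 1
    p = float(sps.chi2.sf(statistic, dof))
    warning = None
    if any(0 < e < 5 for e in expected):
        warning = "expected cell count below 5: chi-square approximation weak"
    return ChiSquareResult(statistic=float(statistic), p_value=p, dof=dof,
                           warning=warning)


# ---------------------------------------------------------------------------
# duplication vs speciation enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    gains_after_duplication: int
    gains_after_speciation: int
    duplication_branch_length: float
    speciation_branch_length: float
    duplication_nodes: int
    speciation_nodes: int
    ratio_branch_length: float | None = None
    ratio_node_count: float | None = None
    flag: str | None = None


def duplication_enrichment(
    events: Sequence[GainEvent], families: Sequence[GeneFamily]
) -> EnrichmentResult:
    """How much more often gains follow duplication than speciation.

    Observed ratio: gains whose parent evolutionary node is a duplication
    over gains after speciation.  Expected ratio under (a) summed branch
    length descending from duplication vs speciation nodes and (b) counts
    of duplication vs speciation internal nodes.  Enrichment is
    observed / expected for each expectation.
    """
    gd = sum(1 for e in events if e.parent_node_kind == DUPLICATION)
    gs = len(events) - gd

    dup_len = spec_len = 0.0
    dup_nodes = spec_nodes = 0
    for fam in families:
        for node in fam.tree.root.walk():
            if node.is_leaf:
                continue
            if node.node_kind == DUPLICATION:
                dup_nodes += 1
                dup_len += sum(c.branch_length for c in node.children)
            else:
                spec_nodes += 1
                spec_len += sum(c.branch_length for c in node.children)

    result = EnrichmentResult(
        gains_after_duplication=gd,
        gains_after_speciation=gs,
        duplication_branch_length=dup_len,
        speciation_branch_length=spec_len,
        duplication_nodes=dup_nodes,
        speciation_nodes=spec_nodes,
    )
    if gs == 0:
        result.flag = "no speciation-associated gains: observed ratio infinite"
        return result
    observed = gd / gs
    if dup_len > 0 and spec_len > 0:
        result.ratio_branch_length = observed / (dup_len / spec_len)
    else:
        result.flag = "zero branch-length share for one node kind"
    if dup_nodes > 0 and spec_nodes > 0:
        result.ratio_node_count = observed / (dup_nodes / spec_nodes)
    elif result.flag is None:
        result.flag = "no nodes of one kind: node-count expectation undefined"
    return result


# ---------------------------------------------------------------------------
# disorder summary
# ---------------------------------------------------------------------------


def disorder_summary(
    classified: Sequence[ClassifiedEvent],
    families: Mapping[str, GeneFamily],
    tracks: Mapping[str, DisorderTrack],
    cfg: ThresholdConfig | None = None,
) -> dict:
    """Mean disordered fraction of gained domains per exon category, and of
    all other domains on the same representative proteins (pooled).

    A residue is disordered when its score is >= ``cfg.disorder_cutoff``.
    Representatives without a track are skipped (noted in the output).
    """
    cfg = cfg or ThresholdConfig()
    per_category: dict[str, list[float]] = {}
    other: list[float] = []
    skipped: list[str] = []
    for ce in classified:
        rep_id = ce.event.representative_transcript
        if rep_id is None:
            continue
        track = tracks.get(rep_id)
        if track is None:
            skipped.append(rep_id)
            continue
        family = families[ce.event.family_id]
        gained = set(ce.event.character_ids)
        for hit in family.hits_on(rep_id):
            frac = track.disordered_fraction(hit.start, hit.end, cfg.disorder_cutoff)
            if hit.character_id in gained:
                per_category.setdefault(ce.structure.exon_category, []).append(frac)
            else:
                other.append(frac)
    out = {
        "gained_by_category": {
            cat: 100.0 * sum(v) / len(v) for cat, v in per_category.items()
        },
        "gained_overall": (
            100.0 * sum(x for v in per_category.values() for x in v)
            / max(sum(len(v) for v in per_category.values()), 1)
        ),
        "other_domains": 100.0 * sum(other) / len(other) if other else 0.0,
        "skipped_missing_track": skipped,
        "omitted_categories": [
            c for c in CATEGORIES if c not in per_category and c != AMBIGUOUS
        ],
    }
    return out


# ---------------------------------------------------------------------------
# funnel report
# ---------------------------------------------------------------------------


def funnel_report(stage_counts: Mapping[str, int]) -> pd.DataFrame:
    """Ordered funnel table with per-stage deltas; enforces monotonicity."""
    stages = [s for s in FUNNEL_STAGES if s in stage_counts]
    stages += [s for s in stage_counts if s not in stages]
    rows = []
    prev: int | None = None
    for s in stages:
        n = stage_counts[s]
        if prev is not None and n > prev:
            raise ValueError(
                f"funnel stage {s!r} has {n} events, more than its "
                f"predecessor ({prev})"
            )
        rows.append({"stage": s, "events": n,
                     "removed": 0 if prev is None else prev - n})
        prev = n
    return pd.DataFrame(rows)


def donor_age_table(
    by_age: Mapping[str, tuple[int, int]]
) -> pd.DataFrame:
    rows = [
        {
            "age_group": g,
            "same_chromosome_donor": n,
            "events": total,
            "percent": percent(n, total),
        }
        for g, (n, total) in by_age.items()
    ]
    return pd.DataFrame(rows)
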