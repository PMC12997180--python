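"""Bias attribution: mapping systematic output differences to provenance.

Divergence between ensemble members becomes clinically interpretable when
it can be traced to documented model characteristics.  This module computes
group-wise analytics along provenance axes:

* geographic / temporal / demographic — mentions-per-model of a target
  diagnosis or term, grouped by a registry axis;
* cost — mean majority-alignment rate of free vs paid models, with a
  bootstrap interval for the difference;
* confidence expression — uncertainty vs confidence marker balance;
* diagnostic diversity — rank correlation between per-case consensus and
  diagnostic breadth.

Spearman rank correlation is used for the breadth-consensus association
because breadth is a heavily right-skewed count.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict
from scipy import stats

from medley.errors import ValidationError
from medley.ingest import ModelResponse
from medley.normalize import AliasTable, canonicalize_label
from medley.registry import Registry, group_by_axis
from medley.stratify import EnsembleAnalytics, ModelConsensusRecord

BiasAxis = Literal[
    "geographic", "temporal", "cost", "demographic", "confidence_expression", "diagnostic_diversity"
]

# provenance axis used to group models for each mention-style bias axis
_GROUPING_FOR_AXIS = {
    "geographic": "origin_region",
    "temporal": "origin_region",
    "demographic": "origin_region",
    "cost": "cost_tier",
}


class GroupStat(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_models: int
    total_mentions: Optional[float] = None
    per_model_rate: Optional[float] = None


class BiasAxisSummary(BaseModel):
    """Group-wise statistics and effect size along one bias axis."""

    model_config = ConfigDict(frozen=True)

    axis: BiasAxis
    target: Optional[str] = None
    group_stats: dict[str, GroupStat]
    effect: Optional[float] = None
    effect_descriptor: str = ""
    normalization: str = "per registered model in group"


def _count_term(text: str, term: str) -> int:
    pattern = re.compile(rf"\b{re.escape(term.lower())}\b", re.IGNORECASE)
    return len(pattern.findall(text))


def _candidate_matches(label: str, target_canonical: str, aliases: AliasTable) -> bool:
    canon = canonicalize_label(label)
    if target_canonical in (canon.canonical, canon.alias):
        return True
    target_group = aliases.group_of(target_canonical)
    if target_group is None:
        return False
    return aliases.group_of(canon.canonical) == target_group or (
        canon.alias is not None and aliases.group_of(canon.alias) == target_group
    )


def mentions_per_model_by_group(
    responses: Iterable[ModelResponse],
    registry: Registry,
    target: str,
    axis: BiasAxis = "geographic",
    *,
    grouping_axis: str | None = None,
    target_kind: Literal["diagnosis", "term"] = "diagnosis",
    aliases: AliasTable | None = None,
) -> BiasAxisSummary:
    """Per-group mentions-per-model of a target diagnosis or free-text term.

    For ``target_kind="diagnosis"`` a mention is a candidate whose label
    matches the target (canonically or via the alias table).  For
    ``target_kind="term"`` mentions are counted in raw response text and
    candidate rationales — suited to temporal (anachronistic condition
    names) and demographic-salience (social-factor terms) analyses.

    The effect is max group rate minus min group rate, with both group
    labels named in the descriptor.  A target nobody mentions yields an
    all-zero summary, not an error.
    """
    grouping = grouping_axis or _GROUPING_FOR_AXIS.get(axis, "origin_region")
    groups = group_by_axis(registry, grouping)
    if aliases is None:
        aliases = AliasTable.default()
    target_canonical = canonicalize_label(target).canonical

    mentions: dict[str, float] = {label: 0.0 for label in groups}
    group_of_model = {mid: label for label, g in groups.items() for mid in g.member_ids}
    for r in responses:
        label = group_of_model.get(r.model_id)
        if label is None:
            continue
        count = 0
        if target_kind == "diagnosis":
            count += sum(1 for c in r.candidates if _candidate_matches(c.label, target_canonical, aliases))
        else:
            if r.raw_text:
                count += _count_term(r.raw_text, target)
            for c in r.candidates:
                if c.rationale_text:
                    count += _count_term(c.rationale_text, target)
        mentions[label] += count

    group_stats = {
        label: GroupStat(
            n_models=groups[label].count,
            total_mentions=mentions[label],
            per_model_rate=mentions[label] / groups[label].count,
        )
        for label in sorted(groups)
    }
    rates = {label: gs.per_model_rate for label, gs in group_stats.items()}
    if rates:
        hi = max(sorted(rates), key=lambda k: rates[k])
        lo = min(sorted(rates), key=lambda k: rates[k])
        effect = rates[hi] - rates[lo]
        descriptor = (
            f"{target!r}: {hi} highest ({rates[hi]:.1f} mentions/model), "
            f"{lo} lowest ({rates[lo]:.1f} mentions/model)"
        )
    else:
        effect, descriptor = None, "empty registry"
    return BiasAxisSummary(
        axis=axis,
        target=target,
        group_stats=group_stats,
        effect=effect,
        effect_descriptor=descriptor,
    )


def alignment_by_cost_tier(
    consensus_records: Sequence[ModelConsensusRecord],
    registry: Registry,
) -> BiasAxisSummary:
    """Mean majority-alignment rate of free vs paid models.

    Effect is the signed difference free minus paid, on the percent scale.
    A tier with no models is reported as null rather than an error.
    """
    tiers: dict[str, list[float]] = {"free": [], "paid": []}
    for rec in consensus_records:
        if rec.model_id not in registry:
            raise ValidationError(f"model {rec.model_id!r} missing from registry")
        if rec.majority_alignment_rate is None:
            continue
        tiers[registry[rec.model_id].cost_tier].append(rec.majority_alignment_rate)

    group_stats = {}
    means: dict[str, Optional[float]] = {}
    for tier in ("free", "paid"):
        vals = tiers[tier]
        mean = float(np.mean(vals)) * 100 if vals else None
        means[tier] = mean
        group_stats[tier] = GroupStat(
            n_models=len(vals),
            total_mentions=None,
            per_model_rate=mean,
        )
    if means["free"] is not None and means["paid"] is not None:
        effect = means["free"] - means["paid"]
        descriptor = (
            f"consensus alignment: free {means['free']:.1f}% vs paid {means['paid']:.1f}%"
        )
    else:
        effect = None
        empty = [t for t, m in means.items() if m is None]
        descriptor = f"tier(s) with no models: {empty}"
    return BiasAxisSummary(
        axis="cost",
        group_stats=group_stats,
        effect=effect,
        effect_descriptor=descriptor,
        normalization="mean alignment per model with a defined rate, as percent",
    )


def bootstrap_cost_effect(
    consensus_records: Sequence[ModelConsensusRecord],
    registry: Registry,
    *,
    n_boot: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the free-minus-paid alignment difference.

    Models are resampled with replacement; resamples that lose an entire
    tier are redrawn implicitly by being skipped (they carry no information
    about the difference).
    """
    rng = rng or np.random.default_rng()
    rates, is_free = [], []
    for rec in consensus_records:
        if rec.majority_alignment_rate is None:
            continue
        rates.append(rec.majority_alignment_rate)
        is_free.append(registry[rec.model_id].cost_tier == "free")
    rates_arr = np.asarray(rates)
    free_arr = np.asarray(is_free)
    n = len(rates_arr)
    if n == 0 or free_arr.all() or not free_arr.any():
        raise ValidationError("bootstrap requires models with defined rates in both tiers")

    idx = rng.integers(0, n, size=(n_boot, n))
    free_mask = free_arr[idx]
    sampled = rates_arr[idx]
    free_mean = np.where(free_mask, sampled, np.nan)
    paid_mean = np.where(~free_mask, sampled, np.nan)
    with warnings.catch_warnings():
        # a resample that loses a whole tier yields nan and is dropped below
        warnings.simplefilter("ignore", RuntimeWarning)
        diffs = (np.nanmean(free_mean, axis=1) - np.nanmean(paid_mean, axis=1)) * 100
    diffs = diffs[np.isfinite(diffs)]
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def marker_balance(
    responses: Iterable[ModelResponse],
) -> tuple[int, int, Literal["uncertainty", "confidence", "neutral"]]:
    """Total uncertainty vs confidence markers across one case's responses."""
    u = c = 0
    for r in responses:
        u += r.uncertainty_marker_count
        c += r.confidence_marker_count
    dominance: Literal["uncertainty", "confidence", "neutral"]
    if u > c:
        dominance = "uncertainty"
    elif c > u:
        dominance = "confidence"
    else:
        dominance = "neutral"
    return u, c, dominance


def breadth_consensus_association(
    analytics: Sequence[EnsembleAnalytics],
) -> Optional[float]:
    """Spearman rank correlation between per-case consensus and breadth.

    Requires at least three cases with a defined consensus rate; a constant
    series has no defined rank correlation and yields ``None``.
    """
    pairs = [
        (a.consensus_rate, a.diagnostic_breadth) for a in analytics if a.consensus_rate is not None
    ]
    if len(pairs) < 3:
        raise ValidationError(
            f"breadth-consensus association needs >= 3 cases with defined consensus, got {len(pairs)}"
        )
    consensus, breadth = zip(*pairs)
    if len(set(consensus)) == 1 or len(set(breadth)) == 1:
        return None
    rho = stats.spearmanr(consensus, breadth).statistic
    return None if np.isnan(rho) else float(rho)
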