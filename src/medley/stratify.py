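"""Agreement-rate stratification of clustered differentials.

For each clustered diagnosis D, the agreement rate is the fraction of
ensemble models proposing D.  Clusters are then stratified:

* PRIMARY      if agreement_rate >= 0.30
* ALTERNATIVE  if 0.10 <= agreement_rate < 0.30
* MINORITY     if agreement_rate < 0.10

Minority diagnoses are never dropped — they are surfaced for rare/atypical
consideration.  Models themselves are categorized by how often they align
with each case's majority cluster: high (>= 60%), moderate ([30%, 60%)),
low (< 30%).

The denominator question matters: a model that timed out expressed no
opinion, so by default rates are taken over responding models only; the
literal all-queried-models denominator is available via
``denominator_policy="all_queried_models"``.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from medley.errors import ValidationError
from medley.ingest import ModelResponse
from medley.normalize import DiagnosisCluster, canonicalize_label

log = logging.getLogger(__name__)

Stratum = Literal["PRIMARY", "ALTERNATIVE", "MINORITY"]
STRATA: tuple[Stratum, ...] = ("PRIMARY", "ALTERNATIVE", "MINORITY")

ConsensusCategory = Literal["high", "moderate", "low"]


class StratificationConfig(BaseModel):
    """Thresholds and denominator policy for stratification."""

    model_config = ConfigDict(frozen=True)

    primary_threshold: float = Field(default=0.30, gt=0.0, le=1.0)
    alternative_threshold: float = Field(default=0.10, gt=0.0)
    model_high_threshold: float = Field(default=0.60, gt=0.0, le=1.0)
    model_moderate_threshold: float = Field(default=0.30, gt=0.0)
    denominator_policy: Literal["responding_models", "all_queried_models"] = "responding_models"

    @model_validator(mode="after")
    def _ordered(self) -> "StratificationConfig":
        if not self.alternative_threshold < self.primary_threshold:
            raise ValueError("alternative_threshold must be < primary_threshold")
        if not self.model_moderate_threshold < self.model_high_threshold:
            raise ValueError("model_moderate_threshold must be < model_high_threshold")
        return self

    def classify_rate(self, rate: float) -> Stratum:
        """Threshold classification of one agreement rate."""
        if rate >= self.primary_threshold:
            return "PRIMARY"
        if rate >= self.alternative_threshold:
            return "ALTERNATIVE"
        return "MINORITY"

    def classify_model_rate(self, rate: float) -> ConsensusCategory:
        if rate >= self.model_high_threshold:
            return "high"
        if rate >= self.model_moderate_threshold:
            return "moderate"
        return "low"


class StratifiedDifferential(BaseModel):
    """The stratified differential for one case."""

    model_config = ConfigDict(frozen=True)

    case_id: str
    strata: dict[Stratum, tuple[DiagnosisCluster, ...]]
    total_models: int = Field(ge=0)
    responding_models: int = Field(ge=0)

    @model_validator(mode="after")
    def _complete(self) -> "StratifiedDifferential":
        missing = [s for s in STRATA if s not in self.strata]
        if missing:
            raise ValueError(f"strata mapping missing {missing}")
        return self

    @property
    def clusters(self) -> list[DiagnosisCluster]:
        """All clusters, PRIMARY first, in within-stratum order."""
        return [c for s in STRATA for c in self.strata[s]]

    @property
    def top_cluster(self) -> Optional[DiagnosisCluster]:
        """Top PRIMARY cluster; if PRIMARY is empty, the highest-rate cluster."""
        if self.strata["PRIMARY"]:
            return self.strata["PRIMARY"][0]
        clusters = self.clusters
        if not clusters:
            return None
        return min(
            clusters,
            key=lambda c: (-(c.agreement_rate or 0.0), -c.mean_confidence, c.canonical_label),
        )


class ModelConsensusRecord(BaseModel):
    """How often one model aligned with the per-case majority cluster."""

    model_config = ConfigDict(frozen=True)

    model_id: str
    cases_evaluated: int = Field(ge=0)
    majority_alignment_rate: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    category: ConsensusCategory

    @property
    def alignment_pct(self) -> Optional[str]:
        """Display form: one-decimal percent (e.g. '83.3%')."""
        if self.majority_alignment_rate is None:
            return None
        return f"{self.majority_alignment_rate * 100:.1f}%"


class EnsembleAnalytics(BaseModel):
    """Per-case descriptive analytics of ensemble behavior."""

    model_config = ConfigDict(frozen=True)

    case_id: str
    consensus_rate: Optional[float] = None  # top-cluster agreement, percent
    diagnostic_breadth: int = Field(ge=0)
    alternative_count: int = Field(ge=0)
    uncertainty_total: int = Field(ge=0)
    confidence_total: int = Field(ge=0)

    @property
    def consensus_display(self) -> Optional[int]:
        """Integer-percent display rounding of the consensus rate."""
        return None if self.consensus_rate is None else round(self.consensus_rate)


def compute_agreement_rates(
    clusters: Iterable[DiagnosisCluster],
    total_models: int,
    responding_models: int,
    config: StratificationConfig | None = None,
) -> list[DiagnosisCluster]:
    """Attach agreement rates: |supporters| / denominator.

    The denominator follows ``config.denominator_policy``; every supporter
    must be among the queried models, so rates lie in (0, 1].
    """
    config = config or StratificationConfig()
    denominator = (
        responding_models if config.denominator_policy == "responding_models" else total_models
    )
    if denominator <= 0:
        raise ValidationError(
            f"zero denominator ({config.denominator_policy}) — no models to count agreement over"
        )
    out = []
    for c in clusters:
        if c.n_supporters > denominator:
            raise ValidationError(
                f"cluster {c.canonical_label!r} has {c.n_supporters} supporters "
                f"but the denominator is only {denominator}"
            )
        out.append(c.model_copy(update={"agreement_rate": c.n_supporters / denominator}))
    return out


def _stratum_sort_key(c: DiagnosisCluster):
    return (-(c.agreement_rate or 0.0), -c.mean_confidence, c.canonical_label)


def stratify_differential(
    clusters: Sequence[DiagnosisCluster],
    config: StratificationConfig | None = None,
    *,
    case_id: str = "",
    total_models: int = 0,
    responding_models: int = 0,
) -> StratifiedDifferential:
    """Partition rate-carrying clusters into the three strata.

    Boundaries are inclusive as printed: a rate equal to the primary
    threshold is PRIMARY; equal to the alternative threshold, ALTERNATIVE.
    Within a stratum, clusters are ordered by agreement rate descending,
    then mean confidence descending, then canonical label ascending.
    """
    config = config or StratificationConfig()
    strata: dict[Stratum, list[DiagnosisCluster]] = {s: [] for s in STRATA}
    for c in clusters:
        if c.agreement_rate is None:
            raise ValidationError(
                f"cluster {c.canonical_label!r} carries no agreement rate; "
                "run compute_agreement_rates first"
            )
        strata[config.classify_rate(c.agreement_rate)].append(c)
    for s in STRATA:
        strata[s].sort(key=_stratum_sort_key)
    return StratifiedDifferential(
        case_id=case_id,
        strata={s: tuple(strata[s]) for s in STRATA},
        total_models=total_models,
        responding_models=responding_models,
    )


def categorize_model_consensus(
    responses_by_case: Mapping[str, Sequence[ModelResponse]],
    stratified_by_case: Mapping[str, StratifiedDifferential],
    config: StratificationConfig | None = None,
    *,
    alignment_mode: Literal["any_candidate", "top1"] = "any_candidate",
    model_ids: Optional[Sequence[str]] = None,
) -> list[ModelConsensusRecord]:
    """Categorize each model by its alignment with per-case majority clusters.

    A model is aligned on a case iff one of its candidates (its rank-1
    candidate only, under ``alignment_mode="top1"``) belongs to that case's
    majority cluster — the top PRIMARY cluster, or the highest-rate cluster
    when PRIMARY is empty.  The alignment rate is taken over the cases the
    model responded to (status ok with at least the empty candidate list).
    When ``model_ids`` is given, listed models that responded to no case
    get an undefined-rate record (category "low", with a warning).
    """
    config = config or StratificationConfig()
    if not responses_by_case:
        raise ValidationError("categorize_model_consensus requires at least one case")

    aligned: dict[str, int] = {}
    evaluated: dict[str, int] = {}
    for case_id, responses in responses_by_case.items():
        stratified = stratified_by_case.get(case_id)
        if stratified is None:
            raise ValidationError(f"no stratified differential for case {case_id!r}")
        top = stratified.top_cluster
        supporters = set(top.supporting_model_ids) if top else set()
        for r in responses:
            if r.status != "ok":
                continue
            evaluated[r.model_id] = evaluated.get(r.model_id, 0) + 1
            if alignment_mode == "top1":
                is_aligned = bool(top) and bool(r.candidates) and (
                    r.model_id in supporters
                    and _top1_in_cluster(r, top)
                )
            else:
                is_aligned = r.model_id in supporters
            if is_aligned:
                aligned[r.model_id] = aligned.get(r.model_id, 0) + 1

    records = []
    for model_id in sorted(evaluated):
        n = evaluated[model_id]
        rate = aligned.get(model_id, 0) / n
        records.append(
            ModelConsensusRecord(
                model_id=model_id,
                cases_evaluated=n,
                majority_alignment_rate=rate,
                category=config.classify_model_rate(rate),
            )
        )
    for model_id in sorted(set(model_ids or ()) - set(evaluated)):
        records.append(zero_case_record(model_id))
    records.sort(key=lambda r: r.model_id)
    return records


def _top1_in_cluster(response: ModelResponse, cluster: DiagnosisCluster) -> bool:
    top_cand = min(response.candidates, key=lambda c: c.rank)
    canon = canonicalize_label(top_cand.label)
    member_canon = {canonicalize_label(lab).canonical for lab in cluster.member_labels}
    return canon.canonical in member_canon or (canon.alias in member_canon)


def zero_case_record(model_id: str) -> ModelConsensusRecord:
    """Record for a model that responded to no cases: undefined rate, low."""
    log.warning("model %s responded to zero cases; alignment rate undefined", model_id)
    return ModelConsensusRecord(
        model_id=model_id, cases_evaluated=0, majority_alignment_rate=None, category="low"
    )


def ensemble_summary(
    stratified: StratifiedDifferential, responses: Iterable[ModelResponse]
) -> EnsembleAnalytics:
    """Per-case analytics: consensus %, breadth, alternatives, marker totals."""
    clusters = stratified.clusters
    top = stratified.top_cluster
    consensus = None if top is None else (top.agreement_rate or 0.0) * 100
    u_total = c_total = 0
    for r in responses:
        u_total += r.uncertainty_marker_count
        c_total += r.confidence_marker_count
    return EnsembleAnalytics(
        case_id=stratified.case_id,
        consensus_rate=consensus,
        diagnostic_breadth=len(clusters),
        alternative_count=max(len(clusters) - 1, 0),
        uncertainty_total=u_total,
        confidence_total=c_total,
    )
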