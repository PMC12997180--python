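"""Plurality-preserving report construction and synthesizer failover.

The report never averages the differential away: in full mode all three
strata appear, every cluster entry cites its supporting models, and each
supporter is annotated with provenance (origin region, cost tier) so a
minority diagnosis from a regional model is surfaced with that context.
Summary mode implements progressive disclosure — only the top consensus
finding plus a summary uncertainty band, with an explicit pointer to the
full report.

Report assembly is template-based and deterministic.  The synthesizer
chain abstraction models failover across pluggable synthesis backends:
backends are tried in order and the first to succeed within its time
budget is used.
"""

from __future__ import annotations

import json
from typing import Callable, Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from medley.errors import MedleyError, SynthesizerExhaustedError, ValidationError
from medley.attribute import BiasAxisSummary
from medley.normalize import DiagnosisCluster
from medley.registry import Registry
from medley.stratify import STRATA, StratifiedDifferential

RenderMode = Literal["summary", "full"]
UncertaintyBand = Literal["high-consensus", "moderate-consensus", "low-consensus"]

# Bands bracket the consensus range heterogeneous ensembles actually produce
# (roughly 50-95% top-cluster agreement); configurable at build time.
DEFAULT_BANDS: tuple[tuple[float, UncertaintyBand], ...] = (
    (80.0, "high-consensus"),
    (60.0, "moderate-consensus"),
)


def uncertainty_band(
    consensus_rate_pct: Optional[float],
    bands: Sequence[tuple[float, UncertaintyBand]] = DEFAULT_BANDS,
) -> Optional[UncertaintyBand]:
    """Deterministic summary band for a consensus rate in percent."""
    if consensus_rate_pct is None:
        return None
    for threshold, label in bands:
        if consensus_rate_pct >= threshold:
            return label
    return "low-consensus"


class SupporterNote(BaseModel):
    model_config = ConfigDict(frozen=True)

    model_id: str
    origin_region: Optional[str] = None
    cost_tier: Optional[str] = None


class ClusterEntry(BaseModel):
    """One annotated diagnosis entry in a report section."""

    model_config = ConfigDict(frozen=True)

    label: str
    icd10_category: Optional[str] = None
    agreement_pct: float
    mean_confidence: float
    supporters: tuple[SupporterNote, ...] = Field(min_length=1)


class Report(BaseModel):
    """Structured, plurality-preserving clinical report for one case."""

    model_config = ConfigDict(frozen=True)

    case_id: str
    generated_at: Optional[str] = None  # ISO timestamp; None keeps artifacts reproducible
    render_mode: RenderMode
    consensus_section: tuple[ClusterEntry, ...]
    alternatives_section: tuple[ClusterEntry, ...]
    minority_section: tuple[ClusterEntry, ...]
    disagreement_notes: tuple[str, ...]
    uncertainty_indicator: Optional[UncertaintyBand]
    no_consensus: bool = False
    no_candidates: bool = False
    expansion_pointer: Optional[str] = None
    synthesizer_used: str = "template"


def _entry(cluster: DiagnosisCluster, registry: Registry | None) -> ClusterEntry:
    notes = []
    for mid in cluster.supporting_model_ids:
        if registry is not None and mid in registry:
            p = registry[mid]
            notes.append(SupporterNote(model_id=mid, origin_region=p.origin_region, cost_tier=p.cost_tier))
        else:
            notes.append(SupporterNote(model_id=mid))
    return ClusterEntry(
        label=cluster.canonical_label,
        icd10_category=cluster.icd10_category,
        agreement_pct=(cluster.agreement_rate or 0.0) * 100,
        mean_confidence=cluster.mean_confidence,
        supporters=tuple(notes),
    )


def _disagreement_notes(
    stratified: StratifiedDifferential,
    registry: Registry | None,
    attribution: Sequence[BiasAxisSummary],
) -> tuple[str, ...]:
    notes = []
    for cluster in stratified.strata["MINORITY"]:
        regions = set()
        for mid in cluster.supporting_model_ids:
            if registry is not None and mid in registry:
                regions.add(registry[mid].origin_region)
        origin = f" (supporting model origin: {', '.join(sorted(regions))})" if regions else ""
        notes.append(
            f"minority diagnosis '{cluster.canonical_label}' proposed by "
            f"{cluster.n_supporters} model(s){origin}; flagged for rare/atypical consideration"
        )
    for summary in attribution:
        if summary.effect_descriptor:
            notes.append(f"{summary.axis} axis: {summary.effect_descriptor}")
    return tuple(notes)


def build_report(
    stratified: StratifiedDifferential,
    registry: Registry | None = None,
    attribution: Sequence[BiasAxisSummary] = (),
    mode: RenderMode = "full",
    *,
    generated_at: str | None = None,
    synthesizer_used: str = "template",
    bands: Sequence[tuple[float, UncertaintyBand]] = DEFAULT_BANDS,
) -> Report:
    """Assemble the clinical report from a stratified differential.

    Full mode carries all three strata with provenance annotations and
    disagreement notes; summary mode carries only the top PRIMARY entry and
    the uncertainty band, with an expansion pointer.  An empty PRIMARY
    stratum leads with a no-consensus banner and the highest-rate cluster;
    an empty differential yields an explicit no-candidates report.
    """
    top = stratified.top_cluster
    if top is None:
        return Report(
            case_id=stratified.case_id,
            generated_at=generated_at,
            render_mode=mode,
            consensus_section=(),
            alternatives_section=(),
            minority_section=(),
            disagreement_notes=(),
            uncertainty_indicator=None,
            no_consensus=True,
            no_candidates=True,
            synthesizer_used=synthesizer_used,
        )

    no_consensus = not stratified.strata["PRIMARY"]
    band = uncertainty_band((top.agreement_rate or 0.0) * 100, bands)

    if mode == "summary":
        return Report(
            case_id=stratified.case_id,
            generated_at=generated_at,
            render_mode="summary",
            consensus_section=(_entry(top, registry),),
            alternatives_section=(),
            minority_section=(),
            disagreement_notes=(),
            uncertainty_indicator=band,
            no_consensus=no_consensus,
            expansion_pointer="full report lists alternative and minority diagnoses",
            synthesizer_used=synthesizer_used,
        )

    primary = stratified.strata["PRIMARY"]
    if no_consensus:
        # lead with the best-supported cluster even without formal consensus
        consensus_entries = (_entry(top, registry),)
    else:
        consensus_entries = tuple(_entry(c, registry) for c in primary)
    return Report(
        case_id=stratified.case_id,
        generated_at=generated_at,
        render_mode="full",
        consensus_section=consensus_entries,
        alternatives_section=tuple(_entry(c, registry) for c in stratified.strata["ALTERNATIVE"]),
        minority_section=tuple(_entry(c, registry) for c in stratified.strata["MINORITY"]),
        disagreement_notes=_disagreement_notes(stratified, registry, attribution),
        uncertainty_indicator=band,
        no_consensus=no_consensus,
        synthesizer_used=synthesizer_used,
    )


_SECTION_HEADINGS = {
    "consensus_section": "## Consensus findings (PRIMARY)",
    "alternatives_section": "## Alternative possibilities (ALTERNATIVE)",
    "minority_section": "## Minority outputs (MINORITY)",
}


def _render_markdown(report: Report) -> str:
    lines = [f"# Differential diagnosis report — case {report.case_id}"]
    if report.generated_at:
        lines.append(f"*Generated: {report.generated_at}*")
    lines.append(f"*Synthesizer: {report.synthesizer_used}; mode: {report.render_mode}*")
    if report.no_candidates:
        lines.append("")
        lines.append("**No candidates** — the ensemble proposed no diagnoses for this case.")
        return "\n".join(lines) + "\n"
    if report.no_consensus:
        lines.append("")
        lines.append("**No consensus** — no diagnosis reached the primary agreement threshold;")
        lines.append("leading with the highest-agreement cluster.")
    if report.uncertainty_indicator:
        lines.append(f"\nUncertainty indicator: **{report.uncertainty_indicator}**")

    def emit(section: str, entries: tuple[ClusterEntry, ...]) -> None:
        lines.append("")
        lines.append(_SECTION_HEADINGS[section])
        if not entries:
            lines.append("*(none)*")
        for e in entries:
            code = f" [{e.icd10_category}]" if e.icd10_category else ""
            lines.append(
                f"- **{e.label}**{code} — agreement {e.agreement_pct:.0f}%, "
                f"mean confidence {e.mean_confidence:.2f}"
            )
            for s in e.supporters:
                prov = ", ".join(x for x in (s.origin_region, s.cost_tier) if x)
                prov = f" ({prov})" if prov else ""
                lines.append(f"  - supported by `{s.model_id}`{prov}")

    if report.render_mode == "summary":
        emit("consensus_section", report.consensus_section)
        if report.expansion_pointer:
            lines.append("")
            lines.append(f"> {report.expansion_pointer}")
    else:
        emit("consensus_section", report.consensus_section)
        emit("alternatives_section", report.alternatives_section)
        emit("minority_section", report.minority_section)
        if report.disagreement_notes:
            lines.append("")
            lines.append("## Disagreement patterns")
            for note in report.disagreement_notes:
                lines.append(f"- {note}")
    return "\n".join(lines) + "\n"


def render(report: Report, format: Literal["markdown", "json"] = "markdown") -> str:
    """Render a report; JSON round-trips losslessly through :func:`read_report`."""
    if format == "json":
        return json.dumps(report.model_dump(), indent=2, ensure_ascii=False)
    if format == "markdown":
        return _render_markdown(report)
    raise ValidationError(f"unknown report format {format!r}; expected 'markdown' or 'json'")


def read_report(document: str) -> Report:
    """Parse a JSON report document back into a :class:`Report`."""
    return Report(**json.loads(document))


class SynthesizerChain(BaseModel):
    """Ordered failover chain of synthesis backends."""

    model_config = ConfigDict(frozen=True)

    synthesizer_ids: tuple[str, ...] = Field(min_length=1)
    timeout_s: float = Field(default=30.0, gt=0)

    @model_validator(mode="after")
    def _unique(self) -> "SynthesizerChain":
        if len(set(self.synthesizer_ids)) != len(self.synthesizer_ids):
            raise ValueError("synthesizer ids must be unique")
        return self


class AttemptRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    synthesizer_id: str
    succeeded: bool
    cause: Optional[str] = None


def select_synthesizer(
    chain: SynthesizerChain,
    availability: Mapping[str, Callable[[], bool]] | Callable[[str], bool],
) -> tuple[str, list[AttemptRecord]]:
    """Try synthesizers in chain order; return the first that succeeds.

    ``availability`` maps each id to a callable probe (or is itself a
    callable of the id) returning truthiness; a raised exception counts as
    a failure with its message as the cause.  Deterministic for a fixed
    availability pattern.  Exhaustion raises
    :class:`SynthesizerExhaustedError` carrying the complete attempt log.
    """
    log: list[AttemptRecord] = []
    for sid in chain.synthesizer_ids:
        try:
            if callable(availability):
                ok = bool(availability(sid))
            else:
                fn = availability.get(sid)
                ok = bool(fn()) if fn is not None else False
            cause = None if ok else "unavailable"
        except Exception as exc:  # a failing probe is a failed attempt, not a crash
            ok, cause = False, f"{type(exc).__name__}: {exc}"
        log.append(AttemptRecord(synthesizer_id=sid, succeeded=ok, cause=cause))
        if ok:
            return sid, log
    raise SynthesizerExhaustedError(
        f"all {len(chain.synthesizer_ids)} synthesizers failed", attempt_log=log
    )
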