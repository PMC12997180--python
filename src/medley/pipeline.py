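"""Composable pipeline: (simulate|ingest) -> stratify -> attribute -> report.

Each stage reads the artifacts of the previous one from the output
directory and writes its own, so stages can run in one invocation or
separately.  A manifest records the stage order, a hash of the effective
configuration, and a checksum for every artifact; with a fixed config and
seed the pipeline is a pure function of its inputs and the checksums are
reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field

from medley.errors import DependencyError, ValidationError
from medley.attribute import (
    alignment_by_cost_tier,
    breadth_consensus_association,
    marker_balance,
    mentions_per_model_by_group,
)
from medley.ingest import MarkerLexicon, load_lexicon, read_responses
from medley.normalize import AliasTable, cluster_candidates
from medley.orchestrate import split_by_case
from medley.registry import Registry, load_registry, write_registry
from medley.simulate import SimulationConfig, simulate_ensemble
from medley.stratify import (
    EnsembleAnalytics,
    ModelConsensusRecord,
    StratificationConfig,
    StratifiedDifferential,
    categorize_model_consensus,
    compute_agreement_rates,
    ensemble_summary,
    stratify_differential,
)
from medley.synthesize import SynthesizerChain, build_report, render, select_synthesizer
from medley.ingest import write_responses

log = logging.getLogger(__name__)

STAGES = ("simulate", "ingest", "stratify", "attribute", "report")


class PipelineConfig(BaseModel):
    """Effective configuration for one pipeline run."""

    model_config = ConfigDict(frozen=True)

    out_dir: Path
    registry_path: Optional[Path] = None
    responses_path: Optional[Path] = None
    lexicon_path: Optional[Path] = None
    alias_path: Optional[Path] = None
    stratification: StratificationConfig = StratificationConfig()
    synthesizer_chain: tuple[str, ...] = ("synth-primary", "synth-backup-1", "synth-backup-2")
    render_mode: str = "full"
    attribution_targets: tuple[str, ...] = ()  # diagnosis labels for mention analysis
    simulation: Optional[SimulationConfig] = None
    seed: Optional[int] = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except pydantic.ValidationError as exc:
            raise ValidationError(f"invalid pipeline config {path}: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, ensure_ascii=False)
        fh.write("\n")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} requires missing artifact {path}")
    return path


def run_pipeline(config: PipelineConfig, stages: Sequence[str]) -> dict:
    """Execute the requested stages; returns the manifest (also on disk).

    Stages must form a dependency-consistent chain: each requested stage
    finds its inputs either on disk (from an earlier run) or produced by an
    earlier requested stage.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stages {unknown}; valid: {STAGES}")
    if "simulate" in stages and "ingest" in stages:
        raise ValidationError("choose either 'simulate' or 'ingest' as the source stage")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lexicon = load_lexicon(config.lexicon_path) if config.lexicon_path else MarkerLexicon.default()
    aliases = AliasTable.load(config.alias_path) if config.alias_path else AliasTable.default()

    artifacts: dict[str, Path] = {}
    executed: list[str] = []

    registry_file = out / "registry.yaml"
    responses_file = out / "responses.jsonl"
    stratified_file = out / "stratified.json"
    analytics_file = out / "analytics.json"
    consensus_file = out / "consensus_records.json"
    attribution_file = out / "attribution.json"

    for stage in stages:
        log.info("stage=%s event=start", stage)
        if stage == "simulate":
            if config.simulation is None:
                raise ValidationError("simulate stage requires a 'simulation' config section")
            sim = config.simulation
            if config.seed is not None:
                sim = sim.model_copy(update={"seed": config.seed})
            registry, responses, truth = simulate_ensemble(sim, lexicon)
            write_registry(registry, registry_file)
            write_responses(responses, responses_file)
            _dump_json(truth.model_dump(mode="json"), out / "truth.json")
            artifacts["registry"] = registry_file
            artifacts["responses"] = responses_file
            artifacts["truth"] = out / "truth.json"

        elif stage == "ingest":
            src_registry = _require(Path(config.registry_path or registry_file), stage)
            src_responses = _require(Path(config.responses_path or responses_file), stage)
            registry = load_registry(src_registry)
            responses = read_responses(src_responses, lexicon)
            if src_registry != registry_file:
                write_registry(registry, registry_file)
            if src_responses != responses_file:
                write_responses(responses, responses_file)
            artifacts["registry"] = registry_file
            artifacts["responses"] = responses_file

        elif stage == "stratify":
            registry = load_registry(_require(registry_file, stage))
            responses = read_responses(_require(responses_file, stage), lexicon)
            by_case = split_by_case(responses)
            stratified_all: dict[str, StratifiedDifferential] = {}
            analytics_all = []
            for case_id, case_responses in by_case.items():
                ok = [r for r in case_responses if r.status == "ok"]
                clusters = cluster_candidates(ok, aliases)
                clusters = compute_agreement_rates(
                    clusters, len(case_responses), max(len(ok), 1), config.stratification
                )
                strat = stratify_differential(
                    clusters,
                    config.stratification,
                    case_id=case_id,
                    total_models=len(case_responses),
                    responding_models=len(ok),
                )
                stratified_all[case_id] = strat
                analytics_all.append(ensemble_summary(strat, case_responses).model_dump())
            _dump_json(
                {cid: s.model_dump(mode="json") for cid, s in stratified_all.items()},
                stratified_file,
            )
            _dump_json(analytics_all, analytics_file)
            records = categorize_model_consensus(by_case, stratified_all, config.stratification)
            _dump_json([r.model_dump() for r in records], consensus_file)
            artifacts["stratified"] = stratified_file
            artifacts["analytics"] = analytics_file
            artifacts["consensus_records"] = consensus_file

        elif stage == "attribute":
            registry = load_registry(_require(registry_file, stage))
            responses = read_responses(_require(responses_file, stage), lexicon)
            _require(consensus_file, stage)
            with open(consensus_file) as fh:
                records = [ModelConsensusRecord(**r) for r in json.load(fh)]
            with open(_require(analytics_file, stage)) as fh:
                analytics = [EnsembleAnalytics(**a) for a in json.load(fh)]
            report: dict = {"normalization_note": "mentions are per registered model in group"}
            report["cost"] = alignment_by_cost_tier(records, registry).model_dump()
            try:
                rho = breadth_consensus_association(analytics)
            except ValidationError:
                rho = None
            report["breadth_consensus_spearman"] = rho
            by_case = split_by_case(responses)
            report["marker_balance"] = {
                cid: dict(zip(("uncertainty_total", "confidence_total", "dominance"), marker_balance(rs)))
                for cid, rs in by_case.items()
            }
            report["mention_targets"] = {
                target: mentions_per_model_by_group(responses, registry, target, aliases=aliases).model_dump()
                for target in config.attribution_targets
            }
            _dump_json(report, attribution_file)
            artifacts["attribution"] = attribution_file

        elif stage == "report":
            registry = load_registry(_require(registry_file, stage))
            _require(stratified_file, stage)
            with open(stratified_file) as fh:
                stratified_all = {
                    cid: StratifiedDifferential(**s) for cid, s in json.load(fh).items()
                }
            chain = SynthesizerChain(synthesizer_ids=config.synthesizer_chain)
            # template backends are always available; the chain records which ran
            chosen, _attempts = select_synthesizer(chain, lambda sid: True)
            for cid, strat in stratified_all.items():
                rep = build_report(
                    strat, registry, mode=config.render_mode, synthesizer_used=chosen  # type: ignore[arg-type]
                )
                (out / f"report_{cid}.json").write_text(render(rep, "json") + "\n")
                (out / f"report_{cid}.md").write_text(render(rep, "markdown"))
                artifacts[f"report_{cid}"] = out / f"report_{cid}.json"
                artifacts[f"report_md_{cid}"] = out / f"report_{cid}.md"

        executed.append(stage)
        log.info("stage=%s event=done", stage)

    manifest = {
        "stages": executed,
        "config_hash": _config_hash(config),
        "seed": config.seed if config.seed is not None else (
            config.simulation.seed if config.simulation else None
        ),
        "artifacts": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in sorted(artifacts.items())},
    }
    _dump_json(manifest, out / "manifest.json")
    return manifest
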