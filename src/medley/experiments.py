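"""Seeded verification studies over the simulator and orchestration logic.

These functions re-derive the package's operating characteristics from
scratch at run time: the stratum and model-category boundaries actually
realized by the classifier, the rate at which bias attribution recovers an
injected regional recognition boost, bootstrap calibration of the
cost-tier comparison under a null, the emergent inverse breadth-consensus
relation across an ambiguity sweep, the failover contract, and pipeline
determinism.  Both the test suite and ``scripts/acceptance.py`` call them.

Problem sizes default to the simulator's study conditions: 30-model
ensembles, 12 cases, 200 seeded replicates for sign-recovery studies and
100 for bootstrap-coverage studies.
"""

from __future__ import annotations

import json
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np

from medley.attribute import (
    alignment_by_cost_tier,
    bootstrap_cost_effect,
    breadth_consensus_association,
    mentions_per_model_by_group,
)
from medley.errors import SynthesizerExhaustedError
from medley.normalize import DiagnosisCluster, cluster_candidates
from medley.orchestrate import split_by_case
from medley.pipeline import PipelineConfig, run_pipeline
from medley.simulate import (
    CaseSpec,
    PoolDiagnosis,
    RegionalTarget,
    SimulationConfig,
    simulate_case_set,
    simulate_ensemble,
)
from medley.stratify import (
    StratificationConfig,
    categorize_model_consensus,
    compute_agreement_rates,
    ensemble_summary,
    stratify_differential,
)
from medley.synthesize import SynthesizerChain, select_synthesizer


def _child_seeds(base_seed: int, n: int) -> list[int]:
    # independent child streams, kept below 2**31 for config validation
    return [int(s) for s in np.random.SeedSequence(base_seed).generate_state(n) % (2**31)]


def _mk_cluster(k: int, label: str = "dx") -> DiagnosisCluster:
    return DiagnosisCluster(
        canonical_label=label,
        member_labels=(label,),
        supporting_model_ids=tuple(f"m{i}" for i in range(k)),
        mean_confidence=0.5,
    )


def stratum_edges(n_models: int = 100, config: StratificationConfig | None = None) -> dict:
    """Sweep support counts k=1..n and measure the realized stratum edges.

    Returns the minimum agreement rate entering the top stratum, the lower
    edge of the middle stratum, the exclusive upper edge of the bottom
    stratum, and the number of distinct strata populated over the sweep.
    """
    config = config or StratificationConfig()
    clusters = [_mk_cluster(k, f"dx-{k:03d}") for k in range(1, n_models + 1)]
    clusters = compute_agreement_rates(clusters, n_models, n_models, config)
    strat = stratify_differential(clusters, config, case_id="sweep",
                                  total_models=n_models, responding_models=n_models)
    rates = {s: [c.agreement_rate for c in strat.strata[s]] for s in strat.strata}
    populated = [s for s, r in rates.items() if r]
    return {
        "primary_min_rate": min(rates["PRIMARY"]),
        "alternative_min_rate": min(rates["ALTERNATIVE"]),
        # smallest rate excluded from the bottom stratum = its exclusive upper edge
        "minority_exclusive_upper_edge": min(rates["ALTERNATIVE"] + rates["PRIMARY"]),
        "minority_max_rate": max(rates["MINORITY"]),
        "n_strata": len(populated),
    }


def model_category_boundaries(
    grid_step: float = 0.001, config: StratificationConfig | None = None
) -> dict:
    """Scan an alignment-rate grid for the realized category boundaries."""
    config = config or StratificationConfig()
    grid = np.round(np.arange(0.0, 1.0 + 1e-12, grid_step), 9)
    cats = [config.classify_model_rate(float(r)) for r in grid]
    high_min = float(grid[cats.index("high")])
    moderate_min = float(grid[cats.index("moderate")])
    return {"high_min_rate": high_min, "moderate_min_rate": moderate_min}


def recovery_case_specs(
    *,
    target: str = "Familial Mediterranean Fever",
    boosted_region: str = "China",
    delta: float = 0.4,
    base_p: float = 0.3,
    n_cases: int = 12,
) -> list[CaseSpec]:
    """Case set for the regional-boost recovery study.

    Every case carries the target at base probability ``base_p`` plus a
    mainstream pool; models from ``boosted_region`` propose the target with
    probability ``base_p + delta``.
    """
    pool = (
        PoolDiagnosis(label="Viral Myocarditis", probability=0.5, icd10_codes=("B33.22",)),
        PoolDiagnosis(label=target, probability=base_p, icd10_codes=("M04.1",)),
        PoolDiagnosis(label="Pericarditis", probability=0.2, icd10_codes=("I30.9",)),
        PoolDiagnosis(label="Anxiety Disorder", probability=0.1, icd10_codes=("F41.9",)),
    )
    return [
        CaseSpec(
            case_id=f"recovery-{i:02d}",
            pool=pool,
            regional_target=RegionalTarget(label=target, region=boosted_region, boost=delta),
            ambiguity=0.3,
            hallucination_rate=0.05,
        )
        for i in range(n_cases)
    ]


def regional_recovery_rate(
    n_runs: int = 200,
    base_seed: int = 0,
    *,
    delta: float = 0.4,
    base_p: float = 0.3,
    n_models: int = 30,
    n_cases: int = 12,
    boosted_region: str = "China",
    target: str = "Familial Mediterranean Fever",
) -> float:
    """Fraction of seeded runs in which attribution recovers the boost.

    A run counts as recovered when the boosted region's mentions/model for
    the target strictly exceeds the pooled rate of all baseline (non-
    boosted) models — the sign of the injected effect.
    """
    specs = recovery_case_specs(
        target=target, boosted_region=boosted_region, delta=delta, base_p=base_p, n_cases=n_cases
    )
    recovered = 0
    for seed in _child_seeds(base_seed, n_runs):
        config = SimulationConfig(n_models=n_models, case_specs=tuple(specs), seed=seed)
        registry, responses, _truth = simulate_ensemble(config)
        summary = mentions_per_model_by_group(responses, registry, target, axis="geographic")
        stats = {g: s for g, s in summary.group_stats.items() if s.n_models > 0}
        boosted = stats.pop(boosted_region, None)
        if boosted is None or not stats:
            continue
        baseline_mentions = sum(s.total_mentions for s in stats.values())
        baseline_models = sum(s.n_models for s in stats.values())
        if boosted.per_model_rate > baseline_mentions / baseline_models:
            recovered += 1
    return recovered / n_runs


def _stratify_run(registry, responses, config: StratificationConfig | None = None):
    config = config or StratificationConfig()
    by_case = split_by_case(responses)
    stratified = {}
    analytics = []
    for case_id, rs in by_case.items():
        ok = [r for r in rs if r.status == "ok"]
        clusters = compute_agreement_rates(cluster_candidates(ok), len(rs), len(ok), config)
        strat = stratify_differential(clusters, config, case_id=case_id,
                                      total_models=len(rs), responding_models=len(ok))
        stratified[case_id] = strat
        analytics.append(ensemble_summary(strat, rs))
    return by_case, stratified, analytics


def cost_calibration_coverage(
    n_runs: int = 100,
    base_seed: int = 0,
    *,
    n_models: int = 30,
    n_boot: int = 1000,
    alphas: Sequence[float] = (0.3, 0.5, 0.7),
    n_cases_per_alpha: int = 4,
) -> float:
    """Null calibration of the free-vs-paid alignment comparison.

    Cost tiers are assigned independently of behavior (no injected cost
    effect), so the bootstrap interval for the free-minus-paid alignment
    difference should cover 0 at close to its nominal 95% rate.
    """
    covered = 0
    for seed in _child_seeds(base_seed, n_runs):
        registry, responses, _truth, _specs = simulate_case_set(
            alphas=alphas, n_cases_per_alpha=n_cases_per_alpha, n_models=n_models, seed=seed
        )
        by_case, stratified, _ = _stratify_run(registry, responses)
        records = categorize_model_consensus(by_case, stratified)
        rng = np.random.default_rng(seed + 1)
        lo, hi = bootstrap_cost_effect(records, registry, n_boot=n_boot, rng=rng)
        if lo <= 0.0 <= hi:
            covered += 1
    return covered / n_runs


def ambiguity_direction_rate(
    n_runs: int = 200,
    base_seed: int = 0,
    *,
    n_models: int = 30,
    alphas: Sequence[float] = (0.1, 0.4, 0.7, 1.0),
    n_cases_per_alpha: int = 3,
) -> float:
    """Fraction of seeded sweep runs with a negative consensus-breadth
    Spearman correlation (the emergent inverse relation)."""
    negative = 0
    for seed in _child_seeds(base_seed, n_runs):
        registry, responses, _truth, _specs = simulate_case_set(
            alphas=alphas, n_cases_per_alpha=n_cases_per_alpha, n_models=n_models, seed=seed
        )
        _, _, analytics = _stratify_run(registry, responses)
        rho = breadth_consensus_association(analytics)
        if rho is not None and rho < 0:
            negative += 1
    return negative / n_runs


def mean_breadth_by_alpha(
    alphas: Sequence[float],
    n_cases_per_alpha: int = 4,
    n_models: int = 30,
    seed: int = 0,
) -> dict[float, float]:
    """Mean diagnostic breadth per ambiguity level in one sweep run."""
    registry, responses, _truth, specs = simulate_case_set(
        alphas=alphas, n_cases_per_alpha=n_cases_per_alpha, n_models=n_models, seed=seed
    )
    alpha_of_case = {s.case_id: s.ambiguity for s in specs}
    _, _, analytics = _stratify_run(registry, responses)
    sums: dict[float, list[int]] = {}
    for a in analytics:
        sums.setdefault(alpha_of_case[a.case_id], []).append(a.diagnostic_breadth)
    return {alpha: float(np.mean(v)) for alpha, v in sums.items()}


def failover_contract_check(chain_ids: Sequence[str] = ("synth-a", "synth-b", "synth-c")) -> float:
    """Exercise every availability pattern of the failover chain.

    For each of the 2^k patterns: the chosen synthesizer must be the first
    available one with an attempt log of exactly that many entries, and the
    all-unavailable pattern must exhaust with a full-length log.  Returns
    the fraction of patterns honoring the contract.
    """
    chain = SynthesizerChain(synthesizer_ids=tuple(chain_ids))
    k = len(chain_ids)
    passed = 0
    for bits in range(2**k):
        pattern = [(bits >> i) & 1 == 1 for i in range(k)]
        availability = dict(zip(chain_ids, pattern))
        try:
            chosen, log = select_synthesizer(chain, lambda sid: availability[sid])
            first_up = pattern.index(True)
            ok = chosen == chain_ids[first_up] and len(log) == first_up + 1
        except SynthesizerExhaustedError as exc:
            ok = not any(pattern) and len(exc.attempt_log) == k
        if ok:
            passed += 1
    return passed / 2**k


def pipeline_determinism_check(seed: int = 17, out_root: str | Path | None = None) -> bool:
    """Run the seeded pipeline twice; compare artifact checksums."""
    sim = SimulationConfig(
        n_models=10,
        case_specs=tuple(recovery_case_specs(n_cases=3)),
        seed=seed,
    )
    manifests = []
    with tempfile.TemporaryDirectory(dir=out_root) as tmp:
        for run in ("a", "b"):
            config = PipelineConfig(
                out_dir=Path(tmp) / run,
                simulation=sim,
                seed=seed,
                attribution_targets=("Familial Mediterranean Fever",),
            )
            manifest = run_pipeline(config, ["simulate", "stratify", "attribute", "report"])
            manifests.append(
                {name: a["sha256"] for name, a in manifest["artifacts"].items()}
            )
    return manifests[0] == manifests[1]
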