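"""Seeded synthetic-ensemble generator.

No deposited model outputs exist for heterogeneous diagnostic ensembles,
and live commercial APIs are irreproducible, so this module generates model
responses with the statistical structure such ensembles exhibit:

* case-dependent consensus — each case carries a diagnosis pool with
  per-diagnosis proposal probabilities; every model proposes each pool
  diagnosis independently (Bernoulli), so agreement rates concentrate
  around the pool probabilities;
* regional recognition boost — a case may name a target diagnosis whose
  proposal probability is raised by delta for models from one region;
* hallucination — with probability ``h`` a model adds an out-of-pool
  diagnosis, preserved downstream as a flagged speculative hypothesis;
* temporal anchoring — with a configurable rate, models propose a term
  from a historical-condition list regardless of case relevance;
* ambiguity-scaled hedging — raw response text carries hedging phrases
  whose expected count is proportional to the case's ambiguity ``alpha``.

Every draw flows through one seeded generator, so a config plus seed fully
determines the output, and the ground truth (realized profiles and the
proposal probabilities actually used) is retained for recovery tests.
All distributions here are this package's own constructions; output
metadata labels them as synthetic.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from medley.errors import ValidationError
from medley.ingest import ClinicalCase, DiagnosisCandidate, MarkerLexicon, ModelResponse, count_markers
from medley.registry import ModelProfile, Registry, REGIONS, PARAMETER_CLASSES

# Out-of-pool diagnoses used for hallucination injection; deliberately
# disjoint from the generated case pools.
HALLUCINATION_POOL: tuple[str, ...] = (
    "Paraneoplastic Syndrome",
    "Systemic Mastocytosis",
    "Erdheim-Chester Disease",
    "Whipple Disease",
    "Hypereosinophilic Syndrome",
    "Amyloidosis",
    "Castleman Disease",
    "POEMS Syndrome",
    "Relapsing Polychondritis",
    "Brucellosis",
)

# Historical conditions over-proposed by temporally anchored models.
HISTORICAL_CONDITIONS: tuple[str, ...] = (
    "HIV/AIDS",
    "Tuberculosis",
    "Syphilis",
    "Rheumatic Fever",
)

_HEDGE_TEMPLATE = "Differential assessment for {case_id}: {labels}."


class PoolDiagnosis(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str = Field(min_length=1)
    probability: float = Field(ge=0.0, le=1.0)
    icd10_codes: tuple[str, ...] = ()


class RegionalTarget(BaseModel):
    """A diagnosis recognized more readily by models from one region."""

    model_config = ConfigDict(frozen=True)

    label: str
    region: str
    boost: float = Field(ge=0.0, le=1.0)  # delta added to the pool probability

    @model_validator(mode="after")
    def _region_known(self) -> "RegionalTarget":
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        return self


class CaseSpec(BaseModel):
    """Generative parameters for one synthetic case."""

    model_config = ConfigDict(frozen=True)

    case_id: str = Field(min_length=1)
    pool: tuple[PoolDiagnosis, ...] = Field(min_length=1)
    regional_target: Optional[RegionalTarget] = None
    ambiguity: float = Field(default=0.3, ge=0.0, le=1.0)
    hallucination_rate: float = Field(default=0.05, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _boost_bounded(self) -> "CaseSpec":
        if self.regional_target is not None:
            by_label = {d.label: d.probability for d in self.pool}
            p = by_label.get(self.regional_target.label)
            if p is None:
                raise ValueError(
                    f"regional target {self.regional_target.label!r} not in the case pool"
                )
            if p + self.regional_target.boost > 1 + 1e-9:
                raise ValueError(
                    f"pool probability {p} + boost {self.regional_target.boost} exceeds 1"
                )
        return self


class SimulationConfig(BaseModel):
    """Full generative configuration; the seed is mandatory."""

    model_config = ConfigDict(frozen=True)

    n_models: int = Field(default=30, ge=1)
    region_distribution: dict[str, float] = {
        # Skewed toward US models, mirroring the composition of current
        # commercial ensembles.
        "US": 0.65,
        "Europe": 0.10,
        "China": 0.16,
        "Other": 0.09,
    }
    cost_tier_split: float = Field(default=0.5, ge=0.0, le=1.0)  # fraction free
    case_specs: tuple[CaseSpec, ...] = Field(min_length=1)
    anachronism_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    hedge_scale: float = Field(default=6.0, ge=0.0)  # expected hedges at alpha=1
    confidence_scale: float = Field(default=2.0, ge=0.0)  # expected confidence markers at alpha=0
    seed: int

    @model_validator(mode="after")
    def _valid_distribution(self) -> "SimulationConfig":
        unknown = set(self.region_distribution) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions in distribution: {sorted(unknown)}")
        total = sum(self.region_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region_distribution sums to {total}, expected 1")
        ids = [c.case_id for c in self.case_specs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate case_id in case_specs")
        return self


class SimulationTruth(BaseModel):
    """Ground truth retained for parameter-recovery tests.

    ``proposal_probabilities[case_id][model_id][label]`` is the Bernoulli
    probability actually used for that (model, case, diagnosis) draw,
    including any regional boost, so every draw is recomputable.
    """

    model_config = ConfigDict(frozen=True)

    seed: int
    profiles: tuple[ModelProfile, ...]
    proposal_probabilities: dict[str, dict[str, dict[str, float]]]
    effects: dict[str, dict[str, float]]  # case_id -> {delta, hallucination_rate, ambiguity}
    generator: str = "synthetic biased-ensemble simulator"


def _draw_profiles(config: SimulationConfig, rng: np.random.Generator) -> list[ModelProfile]:
    regions = sorted(config.region_distribution)
    probs = np.array([config.region_distribution[r] for r in regions])
    region_idx = rng.choice(len(regions), size=config.n_models, p=probs)
    free = rng.random(config.n_models) < config.cost_tier_split
    pclass_idx = rng.integers(0, len(PARAMETER_CLASSES), size=config.n_models)
    day_offsets = rng.integers(0, 3 * 365, size=config.n_models)
    profiles = []
    for i in range(config.n_models):
        profiles.append(
            ModelProfile(
                model_id=f"sim-{i:03d}",
                provider="synthetic",
                origin_region=regions[region_idx[i]],  # type: ignore[arg-type]
                cost_tier="free" if free[i] else "paid",  # type: ignore[arg-type]
                release_date=date(2022, 1, 1) + timedelta(days=int(day_offsets[i])),
                parameter_class=PARAMETER_CLASSES[pclass_idx[i]],  # type: ignore[arg-type]
                architecture_family="transformer",
                intended_scope="synthetic ensemble member",
            )
        )
    return profiles


def _response_for(
    profile: ModelProfile,
    spec: CaseSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    lexicon: MarkerLexicon,
) -> tuple[ModelResponse, dict[str, float]]:
    probs: dict[str, float] = {}
    target = spec.regional_target
    proposed: list[str] = []
    for diag in spec.pool:
        p = diag.probability
        if target is not None and diag.label == target.label and profile.origin_region == target.region:
            p = min(p + target.boost, 1.0)
        probs[diag.label] = p
        if rng.random() < p:
            proposed.append(diag.label)
    codes_by_label = {d.label: d.icd10_codes for d in spec.pool}

    if rng.random() < spec.hallucination_rate:
        label = HALLUCINATION_POOL[rng.integers(0, len(HALLUCINATION_POOL))]
        proposed.append(label)
        codes_by_label.setdefault(label, ())
    if rng.random() < config.anachronism_rate:
        label = HISTORICAL_CONDITIONS[rng.integers(0, len(HISTORICAL_CONDITIONS))]
        if label not in proposed:
            proposed.append(label)
        codes_by_label.setdefault(label, ())

    # order of mention varies across models; ranks follow the mention order
    order = rng.permutation(len(proposed))
    ranked = [proposed[i] for i in order]
    top_conf = rng.uniform(0.6, 0.95)
    candidates = tuple(
        DiagnosisCandidate(
            label=label,
            icd10_codes=codes_by_label.get(label, ()),
            confidence=round(top_conf * 0.85 ** rank, 4),
            rank=rank + 1,
        )
        for rank, label in enumerate(ranked)
    )

    n_hedges = int(rng.poisson(config.hedge_scale * spec.ambiguity))
    n_conf = int(rng.poisson(config.confidence_scale * (1.0 - spec.ambiguity)))
    u_terms = lexicon.uncertainty_terms
    c_terms = lexicon.confidence_terms
    phrases = [u_terms[rng.integers(0, len(u_terms))] for _ in range(n_hedges)]
    phrases += [c_terms[rng.integers(0, len(c_terms))] for _ in range(n_conf)]
    body = _HEDGE_TEMPLATE.format(case_id=spec.case_id, labels="; ".join(ranked) or "none")
    raw_text = body + (" " + ". ".join(phrases) + "." if phrases else "")
    u_count, c_count = count_markers(raw_text, lexicon)

    response = ModelResponse(
        model_id=profile.model_id,
        case_id=spec.case_id,
        status="ok",
        candidates=candidates,
        raw_text=raw_text,
        uncertainty_marker_count=u_count,
        confidence_marker_count=c_count,
    )
    return response, probs


def simulate_ensemble(
    config: SimulationConfig,
    lexicon: MarkerLexicon | None = None,
) -> tuple[Registry, list[ModelResponse], SimulationTruth]:
    """Generate a synthetic ensemble run: registry, responses, ground truth.

    Fully reproducible: the same config (seed included) always yields the
    same profiles and responses, byte-identical when serialized.
    """
    lexicon = lexicon or MarkerLexicon.default()
    rng = np.random.default_rng(config.seed)
    profiles = _draw_profiles(config, rng)
    registry = Registry(profiles)

    responses: list[ModelResponse] = []
    proposal_probs: dict[str, dict[str, dict[str, float]]] = {}
    effects: dict[str, dict[str, float]] = {}
    for spec in config.case_specs:
        per_model: dict[str, dict[str, float]] = {}
        for profile in profiles:
            resp, probs = _response_for(profile, spec, config, rng, lexicon)
            responses.append(resp)
            per_model[profile.model_id] = probs
        proposal_probs[spec.case_id] = per_model
        effects[spec.case_id] = {
            "delta": spec.regional_target.boost if spec.regional_target else 0.0,
            "hallucination_rate": spec.hallucination_rate,
            "ambiguity": spec.ambiguity,
        }
    truth = SimulationTruth(
        seed=config.seed,
        profiles=tuple(profiles),
        proposal_probabilities=proposal_probs,
        effects=effects,
    )
    return registry, responses, truth


# Labels for generated ambiguity-sweep pools: one mainstream diagnosis and a
# long tail of alternatives whose proposal probability grows with ambiguity.
_SWEEP_POOL_LABELS: tuple[str, ...] = (
    "Viral Myocarditis",
    "Pericarditis",
    "Familial Mediterranean Fever",
    "Anxiety Disorder",
    "Pulmonary Embolism",
    "Costochondritis",
    "Gastroesophageal Reflux",
    "Panic Disorder",
    "Acute Coronary Syndrome",
    "Aortic Dissection",
    "Pleuritis",
    "Esophageal Spasm",
    "Sarcoidosis",
    "Systemic Lupus Erythematosus",
    "Adult-Onset Still Disease",
    "Lyme Carditis",
    "Hypothyroidism",
    "Anemia",
    "Chronic Fatigue Syndrome",
    "Endocarditis",
    "Rheumatoid Arthritis",
    "Polymyalgia Rheumatica",
    "Takotsubo Cardiomyopathy",
    "Somatic Symptom Disorder",
)


def sweep_case_spec(case_id: str, alpha: float, *, hallucination_rate: float = 0.05) -> CaseSpec:
    """Case spec whose pool dispersion scales with ambiguity ``alpha``.

    At alpha=0 one diagnosis dominates (p=0.9) and the alternative tail is
    nearly silent, so consensus is high and breadth small; at alpha=1 the
    lead diagnosis drops to p=0.4 while the tail rises (geometric decay
    from ~0.5), flattening the proposal distribution — consensus falls and
    breadth rises along the sweep.
    """
    p_top = 0.9 - 0.5 * alpha
    tail_base = 0.02 + 0.48 * alpha
    pool = [PoolDiagnosis(label=_SWEEP_POOL_LABELS[0], probability=p_top)]
    for i, label in enumerate(_SWEEP_POOL_LABELS[1:], start=1):
        pool.append(PoolDiagnosis(label=label, probability=tail_base * 0.82 ** (i - 1)))
    return CaseSpec(
        case_id=case_id, pool=tuple(pool), ambiguity=alpha, hallucination_rate=hallucination_rate
    )


def simulate_case_set(
    base_config: SimulationConfig | None = None,
    *,
    alphas: Sequence[float],
    n_cases_per_alpha: int,
    n_models: int = 30,
    seed: int,
) -> tuple[Registry, list[ModelResponse], SimulationTruth, list[CaseSpec]]:
    """Generate a case batch spanning an ambiguity gradient.

    Each ambiguity value in ``alphas`` contributes ``n_cases_per_alpha``
    cases built by :func:`sweep_case_spec`; the per-case truth records the
    injected alpha.  When ``base_config`` is given, its ensemble parameters
    (model count, region mix, rates) are reused with the generated cases.
    """
    if not alphas:
        raise ValidationError("ambiguity sweep requires at least one alpha value")
    specs = [
        sweep_case_spec(f"sweep-a{ai}-c{ci}", float(alpha))
        for ai, alpha in enumerate(alphas)
        for ci in range(n_cases_per_alpha)
    ]
    if base_config is not None:
        config = base_config.model_copy(update={"case_specs": tuple(specs), "seed": seed})
    else:
        config = SimulationConfig(n_models=n_models, case_specs=tuple(specs), seed=seed)
    registry, responses, truth = simulate_ensemble(config)
    return registry, responses, truth, specs


def case_for_spec(spec: CaseSpec) -> ClinicalCase:
    """Materialize the clinical-case shell a spec describes (for Stage 1 I/O)."""
    return ClinicalCase(
        case_id=spec.case_id,
        presentation_text=f"Synthetic presentation for {spec.case_id} "
        f"(ambiguity {spec.ambiguity:.2f}).",
        truth_label=spec.pool[0].label,
    )
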