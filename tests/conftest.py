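import pytest

from medley.ingest import DiagnosisCandidate, MarkerLexicon, ModelResponse
from medley.registry import ModelProfile, Registry


@pytest.fixture
def small_registry() -> Registry:
    return Registry(
        [
            ModelProfile(model_id="m1", provider="a", origin_region="US", cost_tier="free"),
            ModelProfile(model_id="m2", provider="a", origin_region="US", cost_tier="paid"),
            ModelProfile(model_id="m3", provider="b", origin_region="Europe", cost_tier="free"),
            ModelProfile(model_id="m4", provider="c", origin_region="China", cost_tier="paid"),
        ]
    )


@pytest.fixture
def lexicon() -> MarkerLexicon:
    return MarkerLexicon(
        uncertainty_terms=("possibly", "cannot rule out", "may", "uncertain"),
        confidence_terms=("clearly", "consistent with", "classic"),
    )


def response(model_id: str, case_id: str, *labels_codes, status: str = "ok", raw_text=None):
    """Build a ModelResponse from (label, codes, confidence) tuples."""
    candidates = tuple(
        DiagnosisCandidate(
            label=label,
            icd10_codes=tuple(codes),
            confidence=conf,
            rank=i + 1,
        )
        for i, (label, codes, conf) in enumerate(labels_codes)
    )
    return ModelResponse(
        model_id=model_id, case_id=case_id, status=status, candidates=candidates, raw_text=raw_text
    )


@pytest.fixture
def mk_response():
    return response
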