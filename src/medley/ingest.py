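"""Parsing of per-model diagnostic outputs.

One model's answer to one clinical case is a ranked list of candidate
diagnoses, each with ICD-10(-CM) codes and a confidence score, plus the raw
response text from which hedging ("possibly", "cannot rule out") and
confidence ("classic", "consistent with") markers are counted against a
declared lexicon.  Responses travel as JSONL, one response per line, which
is also the format the synthetic simulator emits.

Confidence is stored internally as a fraction in [0, 1]; inputs given as
percents (any value > 1, up to 100) are normalized on parse.
"""

from __future__ import annotations

import json
import re
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional

import yaml
import pydantic
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from medley.errors import ValidationError

_DATA_DIR = Path(__file__).parent / "data"

ResponseStatus = Literal["ok", "timeout", "overflow", "error"]

# One letter, two digits, then optionally a dot and 1-4 alphanumerics.
# Covers both ICD-10 (M04.1) and ICD-10-CM (F15.959, T56.0X1A) shapes.
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[A-Z0-9]{1,4})?$")


def validate_icd10(code: str) -> tuple[bool, str]:
    """Validate and normalize an ICD-10(-CM) code.

    Returns ``(is_valid, normalized_code)`` where normalization is
    uppercase + surrounding-whitespace trim.  Invalid codes are returned
    normalized with ``False``; callers decide severity.
    """
    normalized = code.strip().upper()
    return bool(_ICD10_RE.match(normalized)), normalized


class MarkerLexicon(BaseModel):
    """Declared phrase lists for uncertainty and confidence markers.

    The two lists must be disjoint and contain no empty phrases; phrases
    are matched case-insensitively, longest match first, non-overlapping.
    """

    model_config = ConfigDict(frozen=True)

    uncertainty_terms: tuple[str, ...]
    confidence_terms: tuple[str, ...]

    @model_validator(mode="after")
    def _check(self) -> "MarkerLexicon":
        terms = self.uncertainty_terms + self.confidence_terms
        if any(not t.strip() for t in terms):
            raise ValueError("lexicon contains an empty phrase")
        if any(t != t.lower() for t in terms):
            raise ValueError("lexicon phrases must be lowercase")
        overlap = set(self.uncertainty_terms) & set(self.confidence_terms)
        if overlap:
            raise ValueError(f"uncertainty and confidence term lists overlap: {sorted(overlap)}")
        return self

    @classmethod
    def default(cls) -> "MarkerLexicon":
        return load_lexicon(_DATA_DIR / "lexicon.yaml")


def load_lexicon(path: str | Path) -> MarkerLexicon:
    """Load a lexicon from YAML with ``uncertainty:`` and ``confidence:`` lists."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return MarkerLexicon(
            uncertainty_terms=tuple(raw["uncertainty"]),
            confidence_terms=tuple(raw["confidence"]),
        )
    except (KeyError, TypeError, pydantic.ValidationError) as exc:
        raise ValidationError(f"invalid lexicon file {path}: {exc}") from exc


@lru_cache(maxsize=16)
def _phrase_pattern_cached(phrases: tuple[str, ...]) -> re.Pattern:
    alternation = "|".join(re.escape(p) for p in phrases)
    return re.compile(rf"\b(?:{alternation})\b", re.IGNORECASE)


def _phrase_pattern(lexicon: MarkerLexicon) -> re.Pattern:
    # Longest alternative first so "cannot rule out" wins over any shorter
    # phrase starting at the same position; \b anchors avoid substring hits.
    phrases = tuple(sorted(lexicon.uncertainty_terms + lexicon.confidence_terms, key=len, reverse=True))
    return _phrase_pattern_cached(phrases)


def count_markers(text: str, lexicon: MarkerLexicon | None = None) -> tuple[int, int]:
    """Count uncertainty and confidence marker occurrences in free text.

    Case-insensitive, non-overlapping, longest-match-first; counts are
    total occurrences, not distinct terms.
    """
    if lexicon is None:
        lexicon = MarkerLexicon.default()
    if not text:
        return 0, 0
    uncertainty = set(lexicon.uncertainty_terms)
    u = c = 0
    for m in _phrase_pattern(lexicon).finditer(text):
        if m.group(0).lower() in uncertainty:
            u += 1
        else:
            c += 1
    return u, c


class Demographics(BaseModel):
    model_config = ConfigDict(frozen=True)

    age: Optional[float] = Field(default=None, ge=0)
    sex: Optional[Literal["male", "female", "other", "unknown"]] = None
    origin: Optional[str] = None
    social_context: tuple[str, ...] = ()


class ClinicalCase(BaseModel):
    """One clinical vignette presented to every ensemble member."""

    model_config = ConfigDict(frozen=True)

    case_id: str = Field(min_length=1)
    presentation_text: str = Field(min_length=1)
    demographics: Demographics = Demographics()
    truth_label: Optional[str] = None  # simulation ground truth only


class DiagnosisCandidate(BaseModel):
    """One ranked entry in a model's differential."""

    model_config = ConfigDict(frozen=True)

    label: str = Field(min_length=1)
    icd10_codes: tuple[str, ...] = ()
    confidence: float = Field(ge=0.0, le=1.0)
    rank: int = Field(ge=1)
    rationale_text: Optional[str] = None

    @field_validator("icd10_codes", mode="before")
    @classmethod
    def _normalize_codes(cls, v):
        if v is None:
            return ()
        out = []
        for code in v:
            ok, norm = validate_icd10(code)
            if not ok:
                raise ValueError(f"invalid ICD-10 code {code!r}")
            out.append(norm)
        return tuple(out)


class ModelResponse(BaseModel):
    """One model's complete answer to one case, with status bookkeeping."""

    model_config = ConfigDict(frozen=True)

    model_id: str = Field(min_length=1)
    case_id: str = Field(min_length=1)
    status: ResponseStatus = "ok"
    candidates: tuple[DiagnosisCandidate, ...] = ()
    raw_text: Optional[str] = None
    uncertainty_marker_count: int = Field(default=0, ge=0)
    confidence_marker_count: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_ranks(self) -> "ModelResponse":
        ranks = [c.rank for c in self.candidates]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ValueError(f"candidate ranks must be strictly increasing, got {ranks}")
        return self


def _normalize_confidence(value: float) -> float:
    if not 0 <= value <= 100:
        raise ValidationError(f"confidence {value} outside [0, 100]")
    return value / 100 if value > 1 else float(value)


def parse_response(record: dict | str, lexicon: MarkerLexicon | None = None) -> ModelResponse:
    """Parse one JSONL record into a validated :class:`ModelResponse`.

    Marker counts are computed from ``raw_text`` (0 when absent) and
    override any counts in the record; percent confidences are normalized
    to fractions.
    """
    if isinstance(record, str):
        try:
            record = json.loads(record)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"malformed JSONL record: {exc}") from exc
    for field in ("model_id", "case_id", "status"):
        if field not in record:
            raise ValidationError(f"response record missing required field {field!r}")
    status = record["status"]
    if status == "ok" and "candidates" not in record:
        raise ValidationError("status=ok response must carry a candidates list (may be empty)")

    candidates = []
    for cand in record.get("candidates") or ():
        cand = dict(cand)
        if "confidence" in cand:
            cand["confidence"] = _normalize_confidence(cand["confidence"])
        candidates.append(cand)

    raw_text = record.get("raw_text")
    u, c = count_markers(raw_text, lexicon) if raw_text else (0, 0)
    try:
        return ModelResponse(
            model_id=record["model_id"],
            case_id=record["case_id"],
            status=status,
            candidates=tuple(candidates),
            raw_text=raw_text,
            uncertainty_marker_count=u,
            confidence_marker_count=c,
        )
    except pydantic.ValidationError as exc:
        raise ValidationError(f"invalid model response: {exc}") from exc


def write_responses(responses: Iterable[ModelResponse], path: str | Path) -> int:
    """Write responses as JSONL; inverse of :func:`read_responses`."""
    n = 0
    with open(path, "w") as fh:
        for r in responses:
            fh.write(json.dumps(r.model_dump(exclude_none=True), ensure_ascii=False) + "\n")
            n += 1
    return n


def read_responses(path: str | Path, lexicon: MarkerLexicon | None = None) -> list[ModelResponse]:
    """Read a JSONL response file through :func:`parse_response`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_response(line, lexicon))
    return out


def load_cases(path: str | Path) -> list[ClinicalCase]:
    """Load clinical cases from a JSON or YAML document (list of mappings)."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if isinstance(raw, dict) and "cases" in raw:
        raw = raw["cases"]
    if not isinstance(raw, list):
        raise ValidationError(f"case file {path} must contain a list of cases")
    try:
        return [ClinicalCase(**c) for c in raw]
    except pydantic.ValidationError as exc:
        raise ValidationError(f"invalid case in {path}: {exc}") from exc
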