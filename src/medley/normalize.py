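"""Diagnosis-label canonicalization and synonym clustering.

Agreement must be counted over medical concepts, not strings: "FMF",
"Familial Mediterranean Fever" and "Familial Mediterranean Fever (M04.1)"
are one diagnosis.  Candidates from different models are merged when their
canonical labels match, when a curated alias table links them, or when they
share an identical full ICD-10 code; merging is transitive (connected
components of the link graph).

Category-level (3-character) code merging and fuzzy string similarity are
both available but OFF by default: distinct diseases share 3-character
categories, and silent fuzzy merges would hide exactly the minority
diagnoses this system exists to preserve.
"""

from __future__ import annotations

import difflib
import re
import unicodedata
from collections import Counter
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, Field

from medley.errors import ValidationError
from medley.ingest import DiagnosisCandidate, ModelResponse

_DATA_DIR = Path(__file__).parent / "data"

_PARENTHETICAL_RE = re.compile(r"\(([^()]*)\)\s*$")
_APOSTROPHE_RE = re.compile(r"[’']")
_PUNCT_RE = re.compile(r"[^\w\s]")


class CanonicalLabel(NamedTuple):
    canonical: str
    alias: Optional[str]  # trailing parenthetical, itself canonicalized


def _fold(text: str) -> str:
    # accent fold -> lowercase -> drop apostrophes -> punctuation to space
    # -> collapse whitespace ("Wilson's" -> "wilsons", not "wilson s")
    text = unicodedata.normalize("NFKD", text)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = _APOSTROPHE_RE.sub("", text.lower())
    text = _PUNCT_RE.sub(" ", text)
    return " ".join(text.split())


def canonicalize_label(label: str) -> CanonicalLabel:
    """Canonicalize a free-text diagnosis label.

    Lowercases, folds accents, strips punctuation and collapses whitespace.
    A trailing parenthetical — commonly an alternate disease name, e.g.
    "McArdle Disease (Glycogen Storage Disease V)" — is split off and
    returned as a secondary alias.
    """
    if not label or not label.strip():
        raise ValidationError("cannot canonicalize an empty diagnosis label")
    alias = None
    m = _PARENTHETICAL_RE.search(label.strip())
    if m and m.group(1).strip():
        alias = _fold(m.group(1))
        label = label.strip()[: m.start()]
    canonical = _fold(label)
    if not canonical:
        # label was nothing but a parenthetical; promote the alias
        canonical, alias = alias, None
    return CanonicalLabel(canonical=canonical, alias=alias or None)


class AliasTable:
    """Curated synonym table mapping canonical labels into equivalence groups."""

    def __init__(self, groups: dict[str, Sequence[str]] | None = None):
        # map each folded label -> group representative
        self._rep: dict[str, str] = {}
        for canonical, aliases in (groups or {}).items():
            rep = _fold(canonical)
            self._rep[rep] = rep
            for a in aliases:
                self._rep[_fold(a)] = rep

    def group_of(self, canonical_label: str) -> Optional[str]:
        return self._rep.get(canonical_label)

    def with_pair(self, label_a: str, label_b: str) -> "AliasTable":
        """Return a copy in which the two labels are additionally linked."""
        out = AliasTable()
        out._rep = dict(self._rep)
        a, b = _fold(label_a), _fold(label_b)
        rep_a, rep_b = out._rep.get(a, a), out._rep.get(b, b)
        for key, rep in list(out._rep.items()):
            if rep == rep_b:
                out._rep[key] = rep_a
        out._rep[a] = rep_a
        out._rep[b] = rep_a
        return out

    @classmethod
    def load(cls, path: str | Path) -> "AliasTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"alias table {path} must be a mapping canonical -> [aliases]")
        return cls(raw)

    @classmethod
    def default(cls) -> "AliasTable":
        return cls.load(_DATA_DIR / "aliases.yaml")

    @classmethod
    def empty(cls) -> "AliasTable":
        return cls()


class DiagnosisCluster(BaseModel):
    """A group of synonymous candidate diagnoses across models."""

    model_config = ConfigDict(frozen=True)

    canonical_label: str
    member_labels: tuple[str, ...]  # verbatim labels, sorted
    icd10_category: Optional[str] = None  # modal 3-character prefix
    supporting_model_ids: tuple[str, ...]  # sorted, non-empty
    agreement_rate: Optional[float] = Field(default=None, gt=0.0, le=1.0)
    mean_confidence: float = Field(ge=0.0, le=1.0)

    @property
    def n_supporters(self) -> int:
        return len(self.supporting_model_ids)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_candidates(
    responses: Iterable[ModelResponse],
    aliases: AliasTable | None = None,
    *,
    category_level_codes: bool = False,
    fuzzy_threshold: float | None = None,
) -> list[DiagnosisCluster]:
    """Cluster synonymous diagnosis candidates across one case's responses.

    Two candidates merge iff (a) their canonical labels are equal, (b) the
    alias table links them, or (c) they share an identical full ICD-10 code
    (3-character category match instead when ``category_level_codes``).
    Merging is transitive.  ``fuzzy_threshold`` (0-1, via difflib ratio)
    additionally links near-identical canonical labels; it defaults to off.

    A model supports a cluster at most once however many of its candidates
    land there.  The cluster's canonical label is the most frequent verbatim
    member label, ties broken lexicographically.  Agreement rates are left
    unset; the stratification stage fills them against its denominator.
    """
    responses = list(responses)
    if aliases is None:
        aliases = AliasTable.default()
    case_ids = {r.case_id for r in responses}
    if len(case_ids) > 1:
        raise ValidationError(f"cluster_candidates requires a single case, got {sorted(case_ids)}")

    entries: list[tuple[str, DiagnosisCandidate, CanonicalLabel]] = []
    for r in sorted(responses, key=lambda r: r.model_id):
        for cand in r.candidates:
            entries.append((r.model_id, cand, canonicalize_label(cand.label)))
    if not entries:
        return []

    uf = _UnionFind(len(entries))
    by_key: dict[tuple[str, str], int] = {}

    def link(kind: str, key: str, idx: int) -> None:
        prev = by_key.setdefault((kind, key), idx)
        if prev != idx:
            uf.union(prev, idx)

    for i, (_mid, cand, canon) in enumerate(entries):
        labels = [canon.canonical] + ([canon.alias] if canon.alias else [])
        for lab in labels:
            link("label", lab, i)
            group = aliases.group_of(lab)
            if group is not None:
                link("alias", group, i)
        for code in cand.icd10_codes:
            link("code", code[:3] if category_level_codes else code, i)

    if fuzzy_threshold is not None:
        canon_to_idx: dict[str, int] = {}
        for i, (_mid, _c, canon) in enumerate(entries):
            canon_to_idx.setdefault(canon.canonical, i)
        uniq = sorted(canon_to_idx)
        for a_pos, a in enumerate(uniq):
            for b in uniq[a_pos + 1 :]:
                if difflib.SequenceMatcher(None, a, b).ratio() >= fuzzy_threshold:
                    uf.union(canon_to_idx[a], canon_to_idx[b])

    components: dict[int, list[int]] = {}
    for i in range(len(entries)):
        components.setdefault(uf.find(i), []).append(i)

    clusters = []
    for idxs in components.values():
        labels = Counter(entries[i][1].label for i in idxs)
        # most frequent verbatim label; ties broken lexicographically
        best_count = max(labels.values())
        canonical = min(lab for lab, cnt in labels.items() if cnt == best_count)
        supporters = sorted({entries[i][0] for i in idxs})
        codes = [c for i in idxs for c in entries[i][1].icd10_codes]
        category = Counter(c[:3] for c in codes).most_common(1)[0][0] if codes else None
        confs = [entries[i][1].confidence for i in idxs]
        clusters.append(
            DiagnosisCluster(
                canonical_label=canonicalize_label(canonical).canonical,
                member_labels=tuple(sorted(labels)),
                icd10_category=category,
                supporting_model_ids=tuple(supporters),
                mean_confidence=sum(confs) / len(confs),
            )
        )
    clusters.sort(key=lambda c: (-c.n_supporters, c.canonical_label))
    return clusters
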