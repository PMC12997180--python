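"""Model provenance registry.

Every ensemble member carries a provenance record: who built it, where it
originates, whether it is free or paid, when it was released and how large
it is.  Provenance is mandatory in this paradigm — bias attribution is only
possible when divergent outputs can be traced back to documented model
characteristics — so the registry is loaded and validated before any model
is queried.

Regions use a closed four-bucket vocabulary (US, Europe, China, Other).
Free-text country names are mapped onto the buckets via a shipped lookup
table; see :func:`normalize_region`.
"""

from __future__ import annotations

import csv
import logging
import warnings
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional

import yaml
import pydantic
from pydantic import BaseModel, ConfigDict, Field

from medley.errors import ValidationError

log = logging.getLogger(__name__)

Region = Literal["US", "Europe", "China", "Other"]
CostTier = Literal["free", "paid"]
ParameterClass = Literal["small", "medium", "large"]

REGIONS: tuple[str, ...] = ("US", "Europe", "China", "Other")
COST_TIERS: tuple[str, ...] = ("free", "paid")
PARAMETER_CLASSES: tuple[str, ...] = ("small", "medium", "large")

GROUPING_AXES: tuple[str, ...] = ("origin_region", "cost_tier", "parameter_class")

_DATA_DIR = Path(__file__).parent / "data"

_REGISTRY_CSV_HEADER = [
    "model_id",
    "provider",
    "origin_region",
    "cost_tier",
    "release_date",
    "parameter_class",
    "architecture_family",
    "intended_scope",
]


def _load_country_map() -> dict[str, str]:
    with open(_DATA_DIR / "regions.yaml") as fh:
        raw = yaml.safe_load(fh)
    table: dict[str, str] = {}
    for bucket, countries in raw.items():
        for country in countries:
            table[country.strip().lower()] = bucket
    return table


_COUNTRY_MAP: dict[str, str] | None = None


def country_map() -> dict[str, str]:
    """Shipped lookup table: lowercase country/alias -> region bucket."""
    global _COUNTRY_MAP
    if _COUNTRY_MAP is None:
        _COUNTRY_MAP = _load_country_map()
    return _COUNTRY_MAP


def normalize_region(token: str, *, strict: bool = True) -> str:
    """Map a region token onto the four-bucket vocabulary.

    Accepts the bucket names themselves (case-insensitively) and the
    country names in the shipped lookup table.  An unmapped token raises
    :class:`ValidationError` when ``strict`` (the default); otherwise it is
    coerced to ``Other`` with a warning, for registries assembled from
    loosely curated vendor metadata.
    """
    lowered = token.strip().lower()
    if lowered in ("us", "usa", "u.s.", "u.s.a."):
        return "US"
    if lowered in ("europe", "eu"):
        return "Europe"
    if lowered == "china":
        return "China"
    if lowered == "other":
        return "Other"
    mapped = country_map().get(lowered)
    if mapped is not None:
        return mapped
    if strict:
        raise ValidationError(
            f"unknown origin_region token {token!r}; expected one of {REGIONS} or a known country name"
        )
    warnings.warn(f"unmapped origin_region {token!r} coerced to 'Other'", stacklevel=2)
    return "Other"


class ModelProfile(BaseModel):
    """Provenance record for one ensemble member."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    model_id: str = Field(min_length=1)
    provider: str = ""
    origin_region: Region
    cost_tier: CostTier
    release_date: Optional[date] = None
    parameter_class: Optional[ParameterClass] = None
    architecture_family: Optional[str] = None
    intended_scope: Optional[str] = None


class Registry:
    """Ordered collection of :class:`ModelProfile` with unique ids."""

    def __init__(self, profiles: Iterable[ModelProfile] = ()):
        self._profiles: list[ModelProfile] = []
        self._by_id: dict[str, ModelProfile] = {}
        for p in profiles:
            self.add(p)

    def add(self, profile: ModelProfile) -> None:
        if profile.model_id in self._by_id:
            raise ValidationError(f"duplicate model_id {profile.model_id!r} in registry")
        self._by_id[profile.model_id] = profile
        self._profiles.append(profile)

    def __len__(self) -> int:
        return len(self._profiles)

    def __iter__(self) -> Iterator[ModelProfile]:
        return iter(self._profiles)

    def __contains__(self, model_id: str) -> bool:
        return model_id in self._by_id

    def __getitem__(self, model_id: str) -> ModelProfile:
        return self._by_id[model_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Registry):
            return NotImplemented
        return self._profiles == other._profiles

    @property
    def model_ids(self) -> list[str]:
        return [p.model_id for p in self._profiles]


def _profile_from_row(row: dict, *, rownum: int, strict_region: bool) -> ModelProfile:
    data = {k: v for k, v in row.items() if v not in (None, "")}
    if "origin_region" in data:
        try:
            data["origin_region"] = normalize_region(str(data["origin_region"]), strict=strict_region)
        except ValidationError as exc:
            raise ValidationError(f"row {rownum}: {exc}") from exc
    try:
        return ModelProfile(**data)
    except pydantic.ValidationError as exc:
        raise ValidationError(f"row {rownum}: invalid model profile: {exc}") from exc


def load_registry(path: str | Path, format: str | None = None, *, strict_region: bool = True) -> Registry:
    """Load and validate a provenance registry from YAML or CSV.

    File ordering is preserved.  Duplicate ``model_id`` values and unknown
    region/tier tokens raise :class:`ValidationError` naming the offender.
    An empty file yields an empty registry with a logged warning.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "yaml"
    if format not in ("yaml", "csv"):
        raise ValidationError(f"unknown registry format {format!r}; expected 'yaml' or 'csv'")

    rows: list[dict]
    if format == "yaml":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is None:
            raw = []
        if not isinstance(raw, list):
            raise ValidationError(f"registry YAML must be a list of mappings, got {type(raw).__name__}")
        rows = raw
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            rows = list(reader)

    if not rows:
        log.warning("registry file %s is empty", path)

    registry = Registry()
    for i, row in enumerate(rows, start=1):
        registry.add(_profile_from_row(row, rownum=i, strict_region=strict_region))
    log.info("loaded %d model profiles from %s", len(registry), path)
    return registry


def write_registry(registry: Registry, path: str | Path, format: str | None = None) -> None:
    """Serialize a registry; inverse of :func:`load_registry` on valid input."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "yaml"
    if format == "yaml":
        docs = []
        for p in registry:
            d = p.model_dump(exclude_none=True)
            if p.release_date is not None:
                d["release_date"] = p.release_date.isoformat()
            docs.append(d)
        with open(path, "w") as fh:
            yaml.safe_dump(docs, fh, sort_keys=False, allow_unicode=True)
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_REGISTRY_CSV_HEADER)
            writer.writeheader()
            for p in registry:
                d = p.model_dump()
                if p.release_date is not None:
                    d["release_date"] = p.release_date.isoformat()
                writer.writerow({k: ("" if d.get(k) is None else d[k]) for k in _REGISTRY_CSV_HEADER})
    else:
        raise ValidationError(f"unknown registry format {format!r}; expected 'yaml' or 'csv'")


class AxisGroup(BaseModel):
    """One group along a provenance axis."""

    model_config = ConfigDict(frozen=True)

    label: str
    member_ids: tuple[str, ...]
    count: int
    share: float

    @property
    def share_pct(self) -> str:
        """Display form: one-decimal percent."""
        return f"{self.share * 100:.1f}%"


def group_by_axis(registry: Registry, axis: str) -> dict[str, AxisGroup]:
    """Partition the registry along a provenance axis.

    Profiles missing an optional axis value fall into an ``unknown`` group.
    Counts sum to the registry size and shares to 1.
    """
    if axis not in GROUPING_AXES:
        raise ValidationError(f"unknown grouping axis {axis!r}; valid axes: {GROUPING_AXES}")
    members: dict[str, list[str]] = {}
    for p in registry:
        value = getattr(p, axis)
        label = "unknown" if value is None else str(value)
        members.setdefault(label, []).append(p.model_id)
    n = len(registry)
    return {
        label: AxisGroup(label=label, member_ids=tuple(ids), count=len(ids), share=len(ids) / n)
        for label, ids in members.items()
    }
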