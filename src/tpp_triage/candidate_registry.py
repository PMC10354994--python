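"""Candidate-medicine registry: data model, validation and CSV/JSON round-trip.

A registry is an ordered collection of :class:`Candidate` records, each
describing one pipeline medicine: its indication, development phase, product
type, archetype, activity metadata and six curated eligibility-evidence flags.
Validation is strict — enum tokens must come from the closed vocabularies
below, ids must be unique, and update years must not postdate the registry
snapshot year.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping

from .errors import IntegrityError, SchemaError

__all__ = [
    "Indication",
    "Phase",
    "ProductType",
    "Archetype",
    "EligibilityFlags",
    "Candidate",
    "Registry",
    "CLINICAL_PHASES",
    "RANKABLE_PHASES",
    "FLAG_FIELDS",
    "load_registry",
    "write_registry",
    "is_active",
]

DEFAULT_SNAPSHOT_YEAR = 2021
DEFAULT_ACTIVITY_CUTOFF = 2018


class Indication(str, Enum):
    """Whether a candidate targets prevention, management, or both."""

    prevention = "prevention"
    management = "management"
    both = "both"


class Phase(str, Enum):
    preclinical = "preclinical"
    phase1 = "phase1"
    phase2 = "phase2"
    phase3 = "phase3"
    phase4 = "phase4"
    marketed = "marketed"


#: Phases considered "in clinical development" for screening purposes.
CLINICAL_PHASES = frozenset({Phase.phase1, Phase.phase2, Phase.phase3, Phase.phase4})

#: Phases eligible for profile-based ranking.
RANKABLE_PHASES = frozenset({Phase.phase1, Phase.phase2, Phase.phase3})


class ProductType(str, Enum):
    drug = "drug"
    biologic = "biologic"
    dietary_supplement = "dietary_supplement"


class Archetype(str, Enum):
    new_entity = "new_entity"
    repurposed = "repurposed"


#: Eligibility-evidence flag names in criterion order (C1..C6).
FLAG_FIELDS = (
    "marketed_for_indication",
    "who_recommended_or_routine",
    "subgroup_recommended",
    "halted_negative_outcomes",
    "inferior_to_current",
    "other_labour_indication",
)


@dataclass(frozen=True)
class EligibilityFlags:
    """Six curated booleans, one per exclusion criterion.

    These are expert judgements supplied with the registry; they are never
    inferred from the other record fields.
    """

    marketed_for_indication: bool = False
    who_recommended_or_routine: bool = False
    subgroup_recommended: bool = False
    halted_negative_outcomes: bool = False
    inferior_to_current: bool = False
    other_labour_indication: bool = False

    def true_flags(self) -> tuple[str, ...]:
        """Names of the flags that are set, in criterion order."""
        return tuple(name for name in FLAG_FIELDS if getattr(self, name))

    def any(self) -> bool:
        return bool(self.true_flags())


@dataclass(frozen=True, eq=True)
class Candidate:
    """One pipeline medicine.

    ``last_update_year`` is the year of the most recent registry/publication
    activity; ``None`` means unknown.  ``extra`` holds unknown input columns
    as opaque annotations so that round-tripping preserves them.
    """

    id: str
    name: str
    indication: Indication
    phase: Phase
    product_type: ProductType
    archetype: Archetype
    last_update_year: int | None = None
    subclass: str = ""
    route: str | None = None
    flags: EligibilityFlags = field(default_factory=EligibilityFlags)
    extra: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise SchemaError("candidate id must be non-empty")
        if not self.name:
            raise SchemaError(f"candidate {self.id!r}: name must be non-empty")
        for fld, enum_cls in (
            ("indication", Indication),
            ("phase", Phase),
            ("product_type", ProductType),
            ("archetype", Archetype),
        ):
            value = getattr(self, fld)
            if not isinstance(value, enum_cls):
                raise SchemaError(
                    f"candidate {self.id!r}: field {fld!r} must be a "
                    f"{enum_cls.__name__}, got {value!r}"
                )
        if self.last_update_year is not None and self.last_update_year < 1900:
            raise SchemaError(
                f"candidate {self.id!r}: last_update_year "
                f"{self.last_update_year} predates 1900"
            )


@dataclass
class Registry:
    """Ordered, validated collection of candidates."""

    candidates: list[Candidate]
    snapshot_year: int = DEFAULT_SNAPSHOT_YEAR

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cand in self.candidates:
            if cand.id in seen:
                raise IntegrityError(f"duplicate candidate id {cand.id!r}")
            seen.add(cand.id)
            year = cand.last_update_year
            if year is not None and year > self.snapshot_year:
                raise SchemaError(
                    f"candidate {cand.id!r}: last_update_year {year} exceeds "
                    f"snapshot year {self.snapshot_year}"
                )

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self) -> Iterator[Candidate]:
        return iter(self.candidates)

    def by_id(self, candidate_id: str) -> Candidate:
        for cand in self.candidates:
            if cand.id == candidate_id:
                return cand
        raise KeyError(candidate_id)

    def subset(self, phases: frozenset[Phase] | set[Phase]) -> "Registry":
        """New registry keeping only candidates in the given phases."""
        kept = [c for c in self.candidates if c.phase in phases]
        return Registry(kept, snapshot_year=self.snapshot_year)


def is_active(candidate: Candidate, cutoff_year: int = DEFAULT_ACTIVITY_CUTOFF) -> bool:
    """True iff the candidate shows activity at or after ``cutoff_year``.

    Candidates with an unknown update year count as inactive.
    """
    if cutoff_year <= 0:
        raise ValueError("cutoff_year must be positive")
    year = candidate.last_update_year
    return year is not None and year >= cutoff_year


# ---------------------------------------------------------------------------
# serialisation

_BASE_COLUMNS = (
    "id",
    "name",
    "indication",
    "phase",
    "product_type",
    "archetype",
    "last_update_year",
    "subclass",
    "route",
) + FLAG_FIELDS

_TRUE_TOKENS = {"true", "1", "yes"}
_FALSE_TOKENS = {"false", "0", "no", ""}


def _parse_enum(enum_cls: type[Enum], token: str, fld: str, row: int) -> Enum:
    try:
        return enum_cls(token)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise SchemaError(
            f"row {row}: field {fld!r}: unknown token {token!r} "
            f"(expected one of: {allowed})"
        ) from None


def _parse_bool(token: str, fld: str, row: int) -> bool:
    low = str(token).strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise SchemaError(f"row {row}: field {fld!r}: unparseable boolean {token!r}")


def _candidate_from_record(record: Mapping[str, object], row: int) -> Candidate:
    missing = [c for c in _BASE_COLUMNS if c not in record]
    if missing:
        raise SchemaError(f"row {row}: missing required field(s): {', '.join(missing)}")
    year_raw = record["last_update_year"]
    if year_raw is None or str(year_raw).strip() == "":
        year: int | None = None
    else:
        try:
            year = int(str(year_raw))
        except ValueError:
            raise SchemaError(
                f"row {row}: field 'last_update_year': unparseable year {year_raw!r}"
            ) from None
    route_raw = record["route"]
    route = None if route_raw is None or str(route_raw) == "" else str(route_raw)
    flags = EligibilityFlags(
        **{
            name: (
                record[name]
                if isinstance(record[name], bool)
                else _parse_bool(str(record[name]), name, row)
            )
            for name in FLAG_FIELDS
        }
    )
    # blank extras are dropped: a column absent for one row round-trips as ""
    extra = {
        key: str(value)
        for key, value in record.items()
        if key not in _BASE_COLUMNS
        and key != "eligibility_flags"
        and value not in (None, "")
    }
    return Candidate(
        id=str(record["id"]),
        name=str(record["name"]),
        indication=_parse_enum(Indication, str(record["indication"]), "indication", row),
        phase=_parse_enum(Phase, str(record["phase"]), "phase", row),
        product_type=_parse_enum(
            ProductType, str(record["product_type"]), "product_type", row
        ),
        archetype=_parse_enum(Archetype, str(record["archetype"]), "archetype", row),
        last_update_year=year,
        subclass=str(record["subclass"]),
        route=route,
        flags=flags,
        extra=extra,
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"unknown registry format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer registry format from {path.name!r}")


def load_registry(path: str | Path, fmt: str | None = None) -> Registry:
    """Read a registry from CSV or JSON (format inferred from suffix).

    CSV files must carry a header with every base column; unknown columns are
    preserved per candidate.  JSON files hold ``{"snapshot_year": ...,
    "candidates": [...]}`` with the eligibility flags either nested under
    ``eligibility_flags`` or flat.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file, expected a header row")
            missing = [c for c in _BASE_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(
                    f"{path}: header missing required column(s): {', '.join(missing)}"
                )
            candidates = [
                _candidate_from_record(record, row)
                for row, record in enumerate(reader, start=2)
            ]
        return Registry(candidates)
    payload = json.loads(path.read_text(encoding="utf-8"))
    if "candidates" not in payload:
        raise SchemaError(f"{path}: JSON registry must contain a 'candidates' array")
    records = []
    for row, obj in enumerate(payload["candidates"], start=1):
        obj = dict(obj)
        nested = obj.pop("eligibility_flags", None)
        if nested is not None:
            obj.update(nested)
        obj.setdefault("last_update_year", None)
        obj.setdefault("route", None)
        obj.setdefault("subclass", "")
        records.append(_candidate_from_record(obj, row))
    return Registry(records, snapshot_year=int(payload.get("snapshot_year", DEFAULT_SNAPSHOT_YEAR)))


def _candidate_to_record(cand: Candidate) -> dict[str, object]:
    record: dict[str, object] = {
        "id": cand.id,
        "name": cand.name,
        "indication": cand.indication.value,
        "phase": cand.phase.value,
        "product_type": cand.product_type.value,
        "archetype": cand.archetype.value,
        "last_update_year": "" if cand.last_update_year is None else cand.last_update_year,
        "subclass": cand.subclass,
        "route": "" if cand.route is None else cand.route,
    }
    for name in FLAG_FIELDS:
        record[name] = "true" if getattr(cand.flags, name) else "false"
    record.update(cand.extra)
    return record


def write_registry(registry: Registry, path: str | Path, fmt: str | None = None) -> None:
    """Write a registry so that :func:`load_registry` round-trips it exactly."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        extra_cols: list[str] = []
        for cand in registry:
            for key in cand.extra:
                if key not in extra_cols:
                    extra_cols.append(key)
        columns = list(_BASE_COLUMNS) + extra_cols
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.DictWriter(handle, fieldnames=columns, restval="")
            writer.writeheader()
            for cand in registry:
                writer.writerow(_candidate_to_record(cand))
        return
    payload = {
        "snapshot_year": registry.snapshot_year,
        "candidates": [
            {
                **{
                    k: v
                    for k, v in _candidate_to_record(cand).items()
                    if k not in FLAG_FIELDS
                },
                "last_update_year": cand.last_update_year,
                "route": cand.route,
                "eligibility_flags": {
                    name: getattr(cand.flags, name) for name in FLAG_FIELDS
                },
            }
            for cand in registry
        ],
    }
    path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
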