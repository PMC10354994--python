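"""Nine-parameter profile ratings, dual-rater sheets and adjudication.

Each candidate in clinical development is rated against nine critical
product-profile parameters.  Six use the full five-level ordinal scale; the
trial-setting parameter uses a three-level scale (both settings / single
setting / not stated) and the stability and essential-medicines-list
parameters use a binary-plus-unknown scale.  Two raters score each candidate
independently; disagreements are resolved by a third rater.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import SchemaError, UsageError

__all__ = [
    "Parameter",
    "ScaleKind",
    "Level",
    "RatingSheet",
    "AdjudicationResult",
    "PARAMETERS",
    "SCALE_OF",
    "ADMISSIBLE",
    "WEIGHTED_PARAMETERS",
    "CONSENSUS_RATER",
    "parse_level",
    "validate_sheet",
    "adjudicate",
    "agreement_rate",
    "load_sheets",
    "write_sheets",
]


class Parameter(str, Enum):
    setting = "setting"
    efficacy = "efficacy"
    companion_diagnostic = "companion_diagnostic"
    clinical_monitoring = "clinical_monitoring"
    safety = "safety"
    administration = "administration"
    adherence = "adherence"
    stability = "stability"
    eml_listing = "eml_listing"


PARAMETERS: tuple[Parameter, ...] = tuple(Parameter)

#: Parameters that receive greater weight in scoring.
WEIGHTED_PARAMETERS = frozenset({Parameter.efficacy, Parameter.safety})


class ScaleKind(str, Enum):
    ordinal5 = "ordinal5"
    setting3 = "setting3"
    binary_unknown = "binary_unknown"


SCALE_OF: dict[Parameter, ScaleKind] = {
    Parameter.setting: ScaleKind.setting3,
    Parameter.efficacy: ScaleKind.ordinal5,
    Parameter.companion_diagnostic: ScaleKind.ordinal5,
    Parameter.clinical_monitoring: ScaleKind.ordinal5,
    Parameter.safety: ScaleKind.ordinal5,
    Parameter.administration: ScaleKind.ordinal5,
    Parameter.adherence: ScaleKind.ordinal5,
    Parameter.stability: ScaleKind.binary_unknown,
    Parameter.eml_listing: ScaleKind.binary_unknown,
}


class Level(str, Enum):
    """Canonical rating levels, ordered best to worst (unknown apart)."""

    met_preferred = "met_preferred"
    met_minimum = "met_minimum"
    partial_minimum = "partial_minimum"
    not_met = "not_met"
    unknown = "unknown"


#: Restricted-scale aliases accepted on input and mapped to canonical levels.
LEVEL_ALIASES: dict[str, Level] = {
    "both_settings": Level.met_preferred,
    "single_setting": Level.partial_minimum,
    "not_stated": Level.unknown,
    "met": Level.met_preferred,
}

ADMISSIBLE: dict[ScaleKind, frozenset[Level]] = {
    ScaleKind.ordinal5: frozenset(Level),
    ScaleKind.setting3: frozenset(
        {Level.met_preferred, Level.partial_minimum, Level.unknown}
    ),
    ScaleKind.binary_unknown: frozenset(
        {Level.met_preferred, Level.not_met, Level.unknown}
    ),
}

CONSENSUS_RATER = "consensus"


def admissible_levels(parameter: Parameter) -> frozenset[Level]:
    return ADMISSIBLE[SCALE_OF[parameter]]


def parse_level(token: str, parameter: Parameter) -> Level:
    """Map a level token (canonical or alias) to a canonical admissible level."""
    token = token.strip()
    if token in LEVEL_ALIASES:
        level = LEVEL_ALIASES[token]
    else:
        try:
            level = Level(token)
        except ValueError:
            raise SchemaError(
                f"unknown level token {token!r} for parameter {parameter.value!r}"
            ) from None
    if level not in admissible_levels(parameter):
        raise SchemaError(
            f"level {level.value!r} is not admissible for parameter "
            f"{parameter.value!r} (scale {SCALE_OF[parameter].value})"
        )
    return level


@dataclass(frozen=True)
class RatingSheet:
    """One rater's levels for all nine parameters of one candidate."""

    candidate_id: str
    rater_id: str
    levels: Mapping[Parameter, Level]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", dict(self.levels))

    def level(self, parameter: Parameter) -> Level:
        return self.levels[parameter]


def validate_sheet(sheet: RatingSheet) -> RatingSheet:
    """Return the sheet unchanged iff it is complete and scale-admissible."""
    missing = [p.value for p in PARAMETERS if p not in sheet.levels]
    if missing:
        raise SchemaError(
            f"sheet for candidate {sheet.candidate_id!r} is missing "
            f"parameter(s): {', '.join(missing)}"
        )
    unexpected = [p for p in sheet.levels if p not in SCALE_OF]
    if unexpected:
        raise SchemaError(
            f"sheet for candidate {sheet.candidate_id!r} carries unknown "
            f"parameter(s): {unexpected}"
        )
    for parameter, level in sheet.levels.items():
        if not isinstance(level, Level):
            raise SchemaError(
                f"sheet for candidate {sheet.candidate_id!r}: level for "
                f"{parameter.value!r} must be a Level, got {level!r}"
            )
        if level not in admissible_levels(parameter):
            raise SchemaError(
                f"sheet for candidate {sheet.candidate_id!r}: parameter "
                f"{parameter.value!r}: level {level.value!r} is not admissible"
            )
    return sheet


@dataclass(frozen=True)
class AdjudicationResult:
    """Merged consensus sheet plus a record of how it was reached.

    ``unresolved`` lists disagreeing parameters for which no third-rater level
    was available; a non-empty set means the result cannot be scored (the
    merged sheet carries ``unknown`` placeholders for those parameters).
    """

    merged: RatingSheet
    disagreements: tuple[tuple[Parameter, Level, Level], ...]
    resolved_by_third: frozenset[Parameter]
    unresolved: frozenset[Parameter] = field(default_factory=frozenset)

    @property
    def is_resolved(self) -> bool:
        return not self.unresolved


def adjudicate(
    sheet_a: RatingSheet,
    sheet_b: RatingSheet,
    third: Mapping[Parameter, Level] | None = None,
) -> AdjudicationResult:
    """Merge two independent sheets, consulting ``third`` on disagreements.

    Agreeing parameters are copied through.  A disagreeing parameter takes the
    third rater's level when one is provided (and admissible); otherwise it is
    recorded as unresolved and the result is flagged unscorable.
    """
    if sheet_a.candidate_id != sheet_b.candidate_id:
        raise UsageError(
            f"cannot adjudicate sheets for different candidates "
            f"({sheet_a.candidate_id!r} vs {sheet_b.candidate_id!r})"
        )
    validate_sheet(sheet_a)
    validate_sheet(sheet_b)
    third = dict(third or {})
    merged: dict[Parameter, Level] = {}
    disagreements: list[tuple[Parameter, Level, Level]] = []
    resolved: set[Parameter] = set()
    unresolved: set[Parameter] = set()
    for parameter in PARAMETERS:
        level_a = sheet_a.level(parameter)
        level_b = sheet_b.level(parameter)
        if level_a == level_b:
            merged[parameter] = level_a
            continue
        disagreements.append((parameter, level_a, level_b))
        if parameter in third:
            level_c = third[parameter]
            if not isinstance(level_c, Level) or level_c not in admissible_levels(
                parameter
            ):
                raise SchemaError(
                    f"third-rater level {level_c!r} is not admissible for "
                    f"parameter {parameter.value!r}"
                )
            merged[parameter] = level_c
            resolved.add(parameter)
        else:
            merged[parameter] = Level.unknown
            unresolved.add(parameter)
    return AdjudicationResult(
        merged=RatingSheet(sheet_a.candidate_id, CONSENSUS_RATER, merged),
        disagreements=tuple(disagreements),
        resolved_by_third=frozenset(resolved),
        unresolved=frozenset(unresolved),
    )


def agreement_rate(sheet_a: RatingSheet, sheet_b: RatingSheet) -> float:
    """Fraction of the nine parameters on which the two raters agree."""
    if sheet_a.candidate_id != sheet_b.candidate_id:
        raise UsageError(
            f"cannot compare sheets for different candidates "
            f"({sheet_a.candidate_id!r} vs {sheet_b.candidate_id!r})"
        )
    validate_sheet(sheet_a)
    validate_sheet(sheet_b)
    equal = sum(
        1 for p in PARAMETERS if sheet_a.level(p) == sheet_b.level(p)
    )
    return equal / len(PARAMETERS)


# ---------------------------------------------------------------------------
# serialisation

_SHEET_COLUMNS = ("candidate_id", "rater_id") + tuple(p.value for p in PARAMETERS)


def load_sheets(path: str | Path) -> list[RatingSheet]:
    """Read rating sheets from wide CSV or long-format JSON records."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text(encoding="utf-8"))
        if isinstance(records, dict):
            records = records["ratings"]
        by_sheet: dict[tuple[str, str], dict[Parameter, Level]] = {}
        for rec in records:
            key = (str(rec["candidate_id"]), str(rec["rater_id"]))
            parameter = Parameter(rec["parameter"])
            by_sheet.setdefault(key, {})[parameter] = parse_level(
                str(rec["level"]), parameter
            )
        sheets = [
            RatingSheet(cid, rid, levels) for (cid, rid), levels in by_sheet.items()
        ]
    else:
        sheets = []
        with path.open(newline="", encoding="utf-8") as handle:
            reader = csv.DictReader(handle)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty file, expected a header row")
            missing = [c for c in _SHEET_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(
                    f"{path}: header missing column(s): {', '.join(missing)}"
                )
            for record in reader:
                levels = {
                    p: parse_level(record[p.value], p) for p in PARAMETERS
                }
                sheets.append(
                    RatingSheet(record["candidate_id"], record["rater_id"], levels)
                )
    for sheet in sheets:
        validate_sheet(sheet)
    return sheets


def write_sheets(sheets: Iterable[RatingSheet], path: str | Path) -> None:
    """Write sheets as wide CSV (one row per candidate x rater)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_SHEET_COLUMNS)
        for sheet in sheets:
            validate_sheet(sheet)
            writer.writerow(
                [sheet.candidate_id, sheet.rater_id]
                + [sheet.level(p).value for p in PARAMETERS]
            )
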