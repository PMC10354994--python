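"""Candidate x parameter traffic-light matrix with a final-rank column.

Cell colors follow the reporting legend: met preferred (dark green), met
minimum (light green), partially met minimum (yellow), did not meet minimum
(red) and not yet known (grey).  The trial-setting scale maps both settings
to dark green, a single setting to yellow and "not stated" to grey; the
stability and essential-medicines-list scales map met to green (rendered
with the light-green token), not met to red, and unknown to grey.
"""
from __future__ import annotations

import csv
import html as _html
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .candidate_registry import Phase
from .errors import IntegrityError, UsageError
from .scoring_rank import RankResult, Tier
from .tpp_matching import (
    Level,
    PARAMETERS,
    Parameter,
    RatingSheet,
    ScaleKind,
    SCALE_OF,
    admissible_levels,
    validate_sheet,
)

__all__ = [
    "COLOR_TOKENS",
    "MatrixModel",
    "color_map",
    "build_matrix",
    "export_matrix",
    "load_matrix_csv",
]

DARK_GREEN = "dark_green"
LIGHT_GREEN = "light_green"
YELLOW = "yellow"
RED = "red"
GREY = "grey"

COLOR_TOKENS = (DARK_GREEN, LIGHT_GREEN, YELLOW, RED, GREY)

_ORDINAL5_COLORS = {
    Level.met_preferred: DARK_GREEN,
    Level.met_minimum: LIGHT_GREEN,
    Level.partial_minimum: YELLOW,
    Level.not_met: RED,
    Level.unknown: GREY,
}
_SETTING3_COLORS = {
    Level.met_preferred: DARK_GREEN,
    Level.partial_minimum: YELLOW,
    Level.unknown: GREY,
}
_BINARY_COLORS = {
    Level.met_preferred: LIGHT_GREEN,
    Level.not_met: RED,
    Level.unknown: GREY,
}

_SCALE_COLORS = {
    ScaleKind.ordinal5: _ORDINAL5_COLORS,
    ScaleKind.setting3: _SETTING3_COLORS,
    ScaleKind.binary_unknown: _BINARY_COLORS,
}

#: Named colors used by the SVG/HTML exporters.
RENDER_COLORS = {
    DARK_GREEN: "#1e7b1e",
    LIGHT_GREEN: "#8fd18f",
    YELLOW: "#f5d327",
    RED: "#d94040",
    GREY: "#b8b8b8",
}

LEGEND_LINES = (
    "dark green: met preferred | light green: met minimum | "
    "yellow: partially met minimum | red: did not meet minimum | "
    "grey: not yet known",
    "setting: both settings dark green, single setting yellow, "
    "not stated grey",
    "stability / essential-medicines listing: met green, not met red, "
    "unknown grey",
)

FINAL_RANK_COLUMN = "final_rank"


def color_map(parameter: Parameter, level: Level) -> str:
    """Legend color token for an admissible (parameter, level) pair."""
    if level not in admissible_levels(parameter):
        raise ValueError(
            f"level {level.value!r} is not admissible for parameter "
            f"{parameter.value!r}"
        )
    return _SCALE_COLORS[SCALE_OF[parameter]][level]


@dataclass
class MatrixModel:
    """Ordered grid of color tokens plus a tier token per row."""

    rows: list[tuple[str, Phase]]
    columns: tuple[str, ...]
    cells: list[list[str]]

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.cells):
            raise IntegrityError("one cell row required per matrix row")
        for row_cells in self.cells:
            if len(row_cells) != len(self.columns):
                raise IntegrityError("cell row length must match column count")


#: Phase ordering used for row layout (late phases first).
_PHASE_LAYOUT_ORDER = {
    Phase.phase3: 0,
    Phase.phase2: 1,
    Phase.phase1: 2,
}


def build_matrix(
    rank_results: Iterable[RankResult],
    sheets: Mapping[str, RatingSheet],
    names: Mapping[str, str] | None = None,
) -> MatrixModel:
    """Assemble the traffic-light grid from rank results and their sheets.

    Rows are ordered by phase (III, II, I), then descending score fraction,
    then name; every result must have a sheet and vice versa.  ``names``
    optionally maps candidate ids to display names.
    """
    results = list(rank_results)
    result_ids = {r.candidate_id for r in results}
    orphan_results = sorted(result_ids - set(sheets))
    orphan_sheets = sorted(set(sheets) - result_ids)
    if orphan_results or orphan_sheets:
        raise IntegrityError(
            f"rank results without sheets: {orphan_results}; "
            f"sheets without rank results: {orphan_sheets}"
        )
    if len(result_ids) != len(results):
        raise IntegrityError("duplicate candidate ids among rank results")
    ordered = sorted(
        results,
        key=lambda r: (
            _PHASE_LAYOUT_ORDER.get(r.phase, 99),
            -r.score_fraction,
            r.candidate_id,
        ),
    )
    columns = tuple(p.value for p in PARAMETERS) + (FINAL_RANK_COLUMN,)
    rows: list[tuple[str, Phase]] = []
    cells: list[list[str]] = []
    names = names or {}
    for res in ordered:
        sheet = sheets[res.candidate_id]
        validate_sheet(sheet)
        rows.append((names.get(res.candidate_id, res.candidate_id), res.phase))
        cells.append(
            [color_map(p, sheet.level(p)) for p in PARAMETERS] + [res.tier.value]
        )
    return MatrixModel(rows=rows, columns=columns, cells=cells)


# ---------------------------------------------------------------------------
# export

_CSV_PREFIX = ("candidate", "phase")


def export_matrix(matrix: MatrixModel, fmt: str, path: str | Path) -> None:
    """Write the matrix as token CSV, SVG or HTML."""
    path = Path(path)
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(_CSV_PREFIX + matrix.columns)
            for (candidate, phase), row_cells in zip(matrix.rows, matrix.cells):
                writer.writerow([candidate, phase.value] + row_cells)
    elif fmt == "svg":
        path.write_text(_render_svg(matrix), encoding="utf-8")
    elif fmt == "html":
        path.write_text(_render_html(matrix), encoding="utf-8")
    else:
        raise UsageError(f"unknown matrix export format {fmt!r}")


def load_matrix_csv(path: str | Path) -> MatrixModel:
    """Reload a token CSV written by :func:`export_matrix`."""
    with Path(path).open(newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle)
        header = next(reader)
        if tuple(header[:2]) != _CSV_PREFIX:
            raise IntegrityError(f"unexpected matrix CSV header: {header[:2]}")
        columns = tuple(header[2:])
        rows: list[tuple[str, Phase]] = []
        cells: list[list[str]] = []
        for record in reader:
            rows.append((record[0], Phase(record[1])))
            cells.append(record[2:])
    return MatrixModel(rows=rows, columns=columns, cells=cells)


_CELL = 28  # px per cell
_LABEL_W = 220
_HEADER_H = 120


def _cell_fill(token: str) -> str:
    if token in RENDER_COLORS:
        return RENDER_COLORS[token]
    # final-rank column carries tier tokens; shade by tier
    return {
        Tier.high.value: RENDER_COLORS[DARK_GREEN],
        Tier.medium.value: RENDER_COLORS[YELLOW],
        Tier.low.value: RENDER_COLORS[RED],
    }.get(token, "#ffffff")


def _render_svg(matrix: MatrixModel) -> str:
    n_rows, n_cols = len(matrix.rows), len(matrix.columns)
    width = _LABEL_W + n_cols * _CELL + 20
    height = _HEADER_H + n_rows * _CELL + 70
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}">',
        "<!-- color table: "
        + ", ".join(f"{tok}={hexcode}" for tok, hexcode in RENDER_COLORS.items())
        + " -->",
    ]
    for col, name in enumerate(matrix.columns):
        x = _LABEL_W + col * _CELL + _CELL // 2
        parts.append(
            f'<text x="{x}" y="{_HEADER_H - 8}" font-size="10" '
            f'text-anchor="start" transform="rotate(-60 {x} {_HEADER_H - 8})">'
            f"{_html.escape(name)}</text>"
        )
    for row, ((candidate, phase), row_cells) in enumerate(
        zip(matrix.rows, matrix.cells)
    ):
        y = _HEADER_H + row * _CELL
        parts.append(
            f'<text x="4" y="{y + _CELL - 9}" font-size="11">'
            f"{_html.escape(candidate)} ({_html.escape(phase.value)})</text>"
        )
        for col, token in enumerate(row_cells):
            x = _LABEL_W + col * _CELL
            label = "" if token in RENDER_COLORS else token
            parts.append(
                f'<rect class="cell" x="{x}" y="{y}" width="{_CELL - 2}" '
                f'height="{_CELL - 2}" fill="{_cell_fill(token)}" '
                f'stroke="#444"><title>{_html.escape(token)}</title></rect>'
            )
            if label:
                parts.append(
                    f'<text x="{x + 2}" y="{y + _CELL - 10}" font-size="8">'
                    f"{_html.escape(label[:4])}</text>"
                )
    legend_y = _HEADER_H + n_rows * _CELL + 18
    for i, line in enumerate(LEGEND_LINES):
        parts.append(
            f'<text x="4" y="{legend_y + i * 16}" font-size="10">'
            f"{_html.escape(line)}</text>"
        )
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _render_html(matrix: MatrixModel) -> str:
    head = "".join(
        f'<th style="font-size:11px">{_html.escape(c)}</th>' for c in matrix.columns
    )
    body_rows = []
    for (candidate, phase), row_cells in zip(matrix.rows, matrix.cells):
        tds = "".join(
            f'<td class="cell" style="background:{_cell_fill(token)};'
            f'width:26px;height:22px;text-align:center;font-size:9px">'
            f"{_html.escape(token if token not in RENDER_COLORS else '')}</td>"
            for token in row_cells
        )
        body_rows.append(
            f"<tr><td>{_html.escape(candidate)} ({_html.escape(phase.value)})"
            f"</td>{tds}</tr>"
        )
    legend = "".join(f"<p>{_html.escape(line)}</p>" for line in LEGEND_LINES)
    return (
        "<!DOCTYPE html><html><body>"
        f'<table border="1" style="border-collapse:collapse">'
        f"<tr><th>candidate (phase)</th>{head}</tr>{''.join(body_rows)}</table>"
        f"{legend}</body></html>\n"
    )
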