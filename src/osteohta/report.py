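"""Deterministic golden-table writers mirroring the published table layouts.

Each layout renders one of the package's result objects into
semicolon-delimited text (semicolons keep the European thousands separators
unambiguous).  Rendering the same object twice yields identical bytes.
"""

from __future__ import annotations

from decimal import Decimal
from typing import Any, Mapping

import pandas as pd

from .budget_impact import COST_CATEGORIES, BudgetImpact, ScenarioOutcome
from .hospital_costs import FRACTURE_LABELS, AdmissionTable
from .markov_cea import EconomicResult, compute_icer

__all__ = ["render_table", "LAYOUTS"]

LAYOUTS = ("table2", "table3", "table5", "table6", "ceac")

_DELIM = ";"


class LayoutError(TypeError):
    """The result object does not match the requested layout."""


def _fmt_int(x: float) -> str:
    return f"{round(x):,}"


def _fmt_money(x: Decimal | float) -> str:
    return f"{x:,.2f}"


def _lines_to_text(lines: list[list[str]]) -> str:
    return "\n".join(_DELIM.join(cells) for cells in lines) + "\n"


def _render_table2(table: AdmissionTable) -> str:
    lines = [["fracture_type", "admissions", "total_cost_eur"]]
    for label in FRACTURE_LABELS:
        if label not in table.rows:
            continue
        count, cost = table.rows[label]
        lines.append([label, _fmt_int(count), _fmt_money(cost)])
    if table.rows:
        lines.append(["Total", _fmt_int(table.total_admissions), _fmt_money(table.total_cost)])
    return _lines_to_text(lines)


def _render_table3(result: Mapping[str, ScenarioOutcome]) -> str:
    try:
        with_s, without_s = result["with"], result["without"]
    except (KeyError, TypeError):
        raise LayoutError("table3 expects {'with': ScenarioOutcome, 'without': ScenarioOutcome}")
    years = sorted(without_s.fractures)
    lines = [["quantity", *map(str, years)]]
    for ftype, label in (("hip", "Hip/femoral fractures"), ("vertebral", "Vertebral fractures")):
        lines.append(
            [f"{label} (alternatives)"] + [_fmt_int(without_s.fractures[y][ftype]) for y in years]
        )
        lines.append(
            [f"{label} (denosumab)"] + [_fmt_int(with_s.fractures[y][ftype]) for y in years]
        )
        lines.append(
            [f"{label} avoided with denosumab"]
            + [_fmt_int(without_s.fractures[y][ftype] - with_s.fractures[y][ftype]) for y in years]
        )
    return _lines_to_text(lines)


def _render_table5(impact: BudgetImpact) -> str:
    years = impact.years()
    lines = [["category", *map(str, years)]]
    if not years:
        return _lines_to_text(lines)
    keur = impact.in_thousands()
    for cat in COST_CATEGORIES:
        lines.append([cat.capitalize()] + [_fmt_int(keur[y][cat]) for y in years])
    lines.append(["Total"] + [_fmt_int(keur[y]["total"]) for y in years])
    return _lines_to_text(lines)


def _render_table6(result: Mapping[str, Any]) -> str:
    try:
        intervention: EconomicResult = result["intervention"]
        comparators: Mapping[str, EconomicResult] = result["comparators"]
    except (KeyError, TypeError):
        raise LayoutError(
            "table6 expects {'intervention': EconomicResult, 'comparators': {...}}"
        )
    lines = [
        [
            "comparator",
            "cost_intervention",
            "cost_comparator",
            "qalys_intervention",
            "qalys_comparator",
            "delta_cost",
            "delta_qalys",
            "icer_eur_per_qaly",
        ]
    ]
    for name, comp in comparators.items():
        inc = compute_icer(intervention, comp)
        icer_cell = inc.dominance if inc.dominance else _fmt_int(inc.icer)
        lines.append(
            [
                name,
                _fmt_int(intervention.total_cost),
                _fmt_int(comp.total_cost),
                f"{intervention.total_qalys:.2f}",
                f"{comp.total_qalys:.2f}",
                _fmt_int(inc.delta_cost),
                f"{inc.delta_qalys:.4f}",
                icer_cell,
            ]
        )
    return _lines_to_text(lines)


def _render_ceac(frame: pd.DataFrame) -> str:
    if not isinstance(frame, pd.DataFrame) or list(frame.columns) != ["threshold", "probability"]:
        raise LayoutError("ceac expects a DataFrame with columns threshold, probability")
    lines = [["threshold_eur_per_qaly", "probability"]]
    for _, row in frame.iterrows():
        lines.append([f"{row['threshold']:.0f}", f"{row['probability']:.4f}"])
    return _lines_to_text(lines)


def render_table(result: Any, layout: str) -> str:
    """Render a result object in one of the published table layouts.

    Raises :class:`LayoutError` when the result type does not match the
    layout; an empty result yields a header-only table.
    """
    renderers = {
        "table2": (_render_table2, AdmissionTable),
        "table3": (_render_table3, Mapping),
        "table5": (_render_table5, BudgetImpact),
        "table6": (_render_table6, Mapping),
        "ceac": (_render_ceac, pd.DataFrame),
    }
    if layout not in renderers:
        raise LayoutError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")
    renderer, required = renderers[layout]
    if not isinstance(result, required):
        raise LayoutError(f"layout {layout!r} cannot render a {type(result).__name__}")
    return renderer(result)
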