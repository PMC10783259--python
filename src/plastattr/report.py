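"""Rendering of attributable-burden tables.

Formatting is presentation-only: markdown and CSV renderings show values
rounded to a uniform number of significant figures (round-half-even), while
the JSON rendering always carries the unrounded numbers alongside the display
strings, so a JSON report re-parses to the exact table it came from.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

from .attribution import (
    AttributableResult,
    AttributableTable,
    OutcomeBurden,
    Triple,
)
from .prf import PRFTriple

__all__ = [
    "ReportConfig",
    "format_cost",
    "format_percent",
    "render_table",
    "table_from_json",
]


@dataclass(frozen=True)
class ReportConfig:
    """Display precision: significant figures for costs, decimals for percents."""

    sig_figs: int = 3
    percent_decimals: int = 2

    def __post_init__(self):
        if self.sig_figs < 1:
            raise ValueError(f"sig_figs must be >= 1, got {self.sig_figs}")
        if self.percent_decimals < 0:
            raise ValueError("percent_decimals must be nonnegative")


def _round_sig(value: float, sig_figs: int) -> Decimal:
    d = Decimal(repr(value))
    if d == 0:
        return Decimal(0)
    quantum = Decimal(1).scaleb(d.adjusted() - sig_figs + 1)
    return d.quantize(quantum, rounding=ROUND_HALF_EVEN)


def _format_sig(value: float, sig_figs: int) -> str:
    r = _round_sig(value, sig_figs)
    decimals = max(0, sig_figs - 1 - r.adjusted())
    return f"{r:.{decimals}f}"


def format_cost(value: float, config: ReportConfig = ReportConfig()) -> str:
    """Format a cost in billions of USD, e.g. ``22.413 -> "$22.4 billion"``.

    Values below $0.1 billion are rendered in millions.  Rounding is
    round-half-even to ``config.sig_figs`` significant figures.
    """
    if value < 0:
        raise ValueError(f"cost must be nonnegative, got {value}")
    if value == 0:
        return "$0.00 billion"
    if value < 0.1:
        return f"${_format_sig(value * 1000.0, config.sig_figs)} million"
    return f"${_format_sig(value, config.sig_figs)} billion"


def format_percent(fraction: float, config: ReportConfig = ReportConfig()) -> str:
    """Format a fraction as a percent, trimming trailing zeros: 0.975 -> "97.5%"."""
    d = Decimal(repr(fraction * 100.0)).quantize(
        Decimal(1).scaleb(-config.percent_decimals), rounding=ROUND_HALF_EVEN
    )
    text = f"{d:f}"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return f"{text}%"


def _display_rows(table: AttributableTable, config: ReportConfig) -> list[dict]:
    """Rounded display records: outcome rows, class subtotals after their class,
    grand total last (deterministic input order)."""
    rows = []
    class_order = list(table.class_subtotals)
    for cls in class_order:
        for res in table.results:
            if res.burden.chemical_class != cls:
                continue
            b = res.burden
            rows.append(
                {
                    "chemical_class": b.chemical_class,
                    "exposure_chemical": b.exposure_chemical,
                    "life_stage": b.life_stage,
                    "outcome": b.outcome,
                    "prf": "{} ({}-{})".format(
                        format_percent(res.applied_prf.base, config),
                        format_percent(res.applied_prf.low, config),
                        format_percent(res.applied_prf.high, config),
                    ),
                    "attributable_cost": "{} ({} - {})".format(
                        format_cost(res.attributable_cost.base, config),
                        format_cost(res.attributable_cost.low, config),
                        format_cost(res.attributable_cost.high, config),
                    ),
                }
            )
        sub = table.class_subtotals[cls]
        rows.append(
            {
                "chemical_class": cls,
                "exposure_chemical": "All",
                "life_stage": "All",
                "outcome": "All",
                "prf": "",
                "attributable_cost": "{} ({} - {})".format(
                    format_cost(sub.base, config),
                    format_cost(sub.low, config),
                    format_cost(sub.high, config),
                ),
            }
        )
    g = table.grand_total
    rows.append(
        {
            "chemical_class": "All",
            "exposure_chemical": "All",
            "life_stage": "All",
            "outcome": "All",
            "prf": "",
            "attributable_cost": "{} ({} - {})".format(
                format_cost(g.base, config),
                format_cost(g.low, config),
                format_cost(g.high, config),
            ),
        }
    )
    return rows


_DISPLAY_COLUMNS = (
    "chemical_class",
    "exposure_chemical",
    "life_stage",
    "outcome",
    "prf",
    "attributable_cost",
)


def _render_markdown(rows: list[dict]) -> str:
    header = ("Class", "Exposure", "Life stage", "Outcome", "Applied PRF (low-high)",
              "Attributable cost (low - high)")
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(" --- " for _ in header) + "|"]
    for r in rows:
        lines.append("| " + " | ".join(r[c] for c in _DISPLAY_COLUMNS) + " |")
    return "\n".join(lines) + "\n"


def _render_csv(rows: list[dict]) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_DISPLAY_COLUMNS, lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()


def _triple_doc(t: Triple) -> dict:
    return {"base": t.base, "low": t.low, "high": t.high}


def _render_json(table: AttributableTable, rows: list[dict]) -> str:
    doc = {
        "results": [
            {
                "chemical_class": res.burden.chemical_class,
                "exposure_chemical": res.burden.exposure_chemical,
                "life_stage": res.burden.life_stage,
                "outcome": res.burden.outcome,
                "cost": _triple_doc(res.burden.cost),
                "cases": None if res.burden.cases is None else _triple_doc(res.burden.cases),
                "applied_prf": {
                    "base": res.applied_prf.base,
                    "low": res.applied_prf.low,
                    "high": res.applied_prf.high,
                    "chemical_id": res.applied_prf.chemical_id,
                },
                "attributable_cost": _triple_doc(res.attributable_cost),
                "attributable_cases": None
                if res.attributable_cases is None
                else _triple_doc(res.attributable_cases),
            }
            for res in table.results
        ],
        "class_subtotals": {c: _triple_doc(t) for c, t in table.class_subtotals.items()},
        "grand_total": _triple_doc(table.grand_total),
        "display": rows,
    }
    return json.dumps(doc, indent=2)


def render_table(
    table: AttributableTable,
    config: ReportConfig = ReportConfig(),
    fmt: str = "markdown",
) -> str:
    """Render an :class:`AttributableTable` as markdown, CSV, or JSON text.

    All three formats contain identical rounded display values; JSON
    additionally carries the unrounded numbers (see :func:`table_from_json`).
    """
    rows = _display_rows(table, config)
    if fmt in ("markdown", "md"):
        return _render_markdown(rows)
    if fmt == "csv":
        return _render_csv(rows)
    if fmt == "json":
        return _render_json(table, rows)
    raise ValueError(f"unknown report format {fmt!r}; expected markdown, csv or json")


def _triple_from_doc(doc) -> Triple:
    return Triple(doc["base"], doc["low"], doc["high"])


def table_from_json(text: str) -> AttributableTable:
    """Re-parse a JSON report into the exact table object that produced it."""
    doc = json.loads(text)
    results = []
    for r in doc["results"]:
        burden = OutcomeBurden(
            chemical_class=r["chemical_class"],
            exposure_chemical=r["exposure_chemical"],
            life_stage=r["life_stage"],
            outcome=r["outcome"],
            cost=_triple_from_doc(r["cost"]),
            cases=None if r["cases"] is None else _triple_from_doc(r["cases"]),
        )
        prf_doc = r["applied_prf"]
        prf = PRFTriple(
            base=prf_doc["base"],
            low=prf_doc["low"],
            high=prf_doc["high"],
            chemical_id=prf_doc.get("chemical_id", ""),
        )
        results.append(
            AttributableResult(
                burden=burden,
                applied_prf=prf,
                attributable_cost=_triple_from_doc(r["attributable_cost"]),
                attributable_cases=None
                if r["attributable_cases"] is None
                else _triple_from_doc(r["attributable_cases"]),
            )
        )
    return AttributableTable(
        results=tuple(results),
        class_subtotals={
            c: _triple_from_doc(t) for c, t in doc["class_subtotals"].items()
        },
        grand_total=_triple_from_doc(doc["grand_total"]),
    )
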