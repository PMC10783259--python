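"""Attribution of disease-burden costs and cases to plastic-related exposure.

Each burden row (one chemical class / life stage / outcome with a base-low-high
cost triple, optionally case counts) is matched to an attribution rule that
names the chemical whose PRF applies in the base case and the set of chemicals
whose PRF bounds form the sensitivity envelope — e.g. outcomes costed from
PFOA exposure take the PFOA base PRF but a low bound from PFOS, whose
plastic-related share is far smaller.

Attribution itself is a componentwise product under the proportionality
assumption, paired multiway: lowest PRF bound with lowest cost bound, highest
with highest, never crossed.  Aggregation sums componentwise within each
chemical class and overall.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, NamedTuple, Sequence

import yaml

from .errors import BurdenParseError, PRFLookupError, RuleError
from .prf import PRFTriple

__all__ = [
    "Triple",
    "OutcomeBurden",
    "AttributionRule",
    "AttributableResult",
    "AttributableTable",
    "resolve_prf",
    "attribute",
    "aggregate",
    "attribute_table",
    "read_burden_table",
    "write_burden_table",
    "read_rules",
]

WILDCARD = "*"


class Triple(NamedTuple):
    """A (base, low, high) estimate triple — costs in billions of USD, or cases."""

    base: float
    low: float
    high: float


def _as_triple(value) -> Triple:
    if isinstance(value, Triple):
        return value
    return Triple(*map(float, value))


@dataclass(frozen=True)
class OutcomeBurden:
    """One disease-burden row: total cost (and optional cases) for an outcome.

    Costs are base/low/high in billions of 2018 USD across exposure routes,
    *before* any plastic attribution.  ``cases`` uses whatever unit the source
    states (persons, IQ points, ...) and may be absent.
    """

    chemical_class: str
    exposure_chemical: str
    life_stage: str
    outcome: str
    cost: Triple
    cases: Triple | None = None

    def __post_init__(self):
        object.__setattr__(self, "cost", _as_triple(self.cost))
        if self.cases is not None:
            object.__setattr__(self, "cases", _as_triple(self.cases))
        for t, label in ((self.cost, "cost"), (self.cases, "cases")):
            if t is None:
                continue
            if min(t) < 0:
                raise ValueError(f"{label} components must be nonnegative: {t}")
            if not t.low <= t.base <= t.high:
                raise ValueError(
                    f"{label} triple must satisfy low <= base <= high, got {t} "
                    f"({self.chemical_class}/{self.outcome})"
                )


@dataclass(frozen=True)
class AttributionRule:
    """Maps burden rows to the PRF source chemical(s).

    ``match_class`` / ``match_outcome`` select rows (``"*"`` is a wildcard;
    the most specific matching rule wins).  Either a computed-PRF mapping
    (``base_prf_chemical`` plus ``envelope_prf_chemicals``) or an explicit
    ``prf_override`` triple must be given; an override takes precedence and
    is applied verbatim.
    """

    match_class: str = WILDCARD
    match_outcome: str = WILDCARD
    base_prf_chemical: str | None = None
    envelope_prf_chemicals: tuple[str, ...] = ()
    prf_override: PRFTriple | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "envelope_prf_chemicals", tuple(self.envelope_prf_chemicals)
        )
        if self.prf_override is None:
            if self.base_prf_chemical is None:
                raise RuleError(
                    f"rule {self._label()}: needs base_prf_chemical or prf_override"
                )
            if not self.envelope_prf_chemicals:
                # single-chemical envelope defaults to the base chemical
                object.__setattr__(
                    self, "envelope_prf_chemicals", (self.base_prf_chemical,)
                )

    def _label(self) -> str:
        return f"({self.match_class}, {self.match_outcome})"

    def matches(self, row: OutcomeBurden) -> bool:
        return self.match_class in (WILDCARD, row.chemical_class) and self.match_outcome in (
            WILDCARD,
            row.outcome,
        )

    @property
    def specificity(self) -> int:
        return (self.match_class != WILDCARD) + (self.match_outcome != WILDCARD)


@dataclass(frozen=True)
class AttributableResult:
    """Attribution output for one burden row."""

    burden: OutcomeBurden
    applied_prf: PRFTriple
    attributable_cost: Triple
    attributable_cases: Triple | None = None


@dataclass(frozen=True)
class AttributableTable:
    """Per-outcome results with class subtotals and the grand total (cost triples)."""

    results: tuple[AttributableResult, ...]
    class_subtotals: dict[str, Triple]
    grand_total: Triple

    def __post_init__(self):
        object.__setattr__(self, "results", tuple(self.results))


def resolve_prf(
    row: OutcomeBurden,
    rules: Sequence[AttributionRule],
    prfs: Mapping[str, PRFTriple],
) -> PRFTriple:
    """Select the PRF triple applied to a burden row.

    The most specific matching rule wins.  The base component comes from the
    rule's base chemical; the low (high) bound is the minimum low (maximum
    high) over the rule's envelope chemicals, so a sensitivity envelope can
    span several plausible exposure sources.

    Raises
    ------
    RuleError
        If no rule matches the row, or two distinct rules tie at the highest
        specificity.
    PRFLookupError
        If a rule names a chemical absent from ``prfs``.
    """
    matching = [r for r in rules if r.matches(row)]
    if not matching:
        raise RuleError(
            f"no attribution rule matches row ({row.chemical_class!r}, {row.outcome!r})"
        )
    top = max(r.specificity for r in matching)
    best = [r for r in matching if r.specificity == top]
    if len(best) > 1:
        raise RuleError(
            f"ambiguous rules for row ({row.chemical_class!r}, {row.outcome!r}): "
            + ", ".join(r._label() for r in best)
        )
    rule = best[0]
    if rule.prf_override is not None:
        return rule.prf_override
    try:
        base = prfs[rule.base_prf_chemical].base
        lows = [prfs[c].low for c in rule.envelope_prf_chemicals]
        highs = [prfs[c].high for c in rule.envelope_prf_chemicals]
    except KeyError as exc:
        raise PRFLookupError(
            f"rule {rule._label()} references chemical {exc.args[0]!r} "
            "with no available PRF triple"
        ) from exc
    return PRFTriple(
        base=base,
        low=min(lows),
        high=max(highs),
        chemical_id=rule.base_prf_chemical,
    )


def attribute(row: OutcomeBurden, prf: PRFTriple) -> AttributableResult:
    """Multiply a burden row by a PRF triple, componentwise.

    The multiway sensitivity pairing is fixed: low PRF with low cost, high
    PRF with high cost — no cross terms.  Case counts, when present, flow
    through the identical product.
    """
    cost = Triple(
        row.cost.base * prf.base, row.cost.low * prf.low, row.cost.high * prf.high
    )
    cases = None
    if row.cases is not None:
        cases = Triple(
            row.cases.base * prf.base, row.cases.low * prf.low, row.cases.high * prf.high
        )
    return AttributableResult(
        burden=row, applied_prf=prf, attributable_cost=cost, attributable_cases=cases
    )


def aggregate(results: Sequence[AttributableResult]) -> AttributableTable:
    """Sum attributable costs componentwise per chemical class and overall.

    Class subtotals follow the order classes first appear in ``results``;
    low/high subtotals are sums of the row lows/highs (the all-low / all-high
    multiway convention).
    """
    results = tuple(results)
    if not results:
        raise ValueError("aggregate() requires at least one result")
    subtotals: dict[str, list[float]] = {}
    grand = [0.0, 0.0, 0.0]
    for res in results:
        acc = subtotals.setdefault(res.burden.chemical_class, [0.0, 0.0, 0.0])
        for k in range(3):
            acc[k] += res.attributable_cost[k]
            grand[k] += res.attributable_cost[k]
    return AttributableTable(
        results=results,
        class_subtotals={c: Triple(*acc) for c, acc in subtotals.items()},
        grand_total=Triple(*grand),
    )


def attribute_table(
    rows: Sequence[OutcomeBurden],
    rules: Sequence[AttributionRule],
    prfs: Mapping[str, PRFTriple],
) -> AttributableTable:
    """Resolve, attribute and aggregate a whole burden table in one call."""
    return aggregate([attribute(row, resolve_prf(row, rules, prfs)) for row in rows])


# ---------------------------------------------------------------------------
# I/O

_BURDEN_COLUMNS = (
    "chemical_class",
    "exposure_chemical",
    "life_stage",
    "outcome",
    "cost_base",
    "cost_low",
    "cost_high",
    "cases_base",
    "cases_low",
    "cases_high",
)


def read_burden_table(source: str | Path | IO[str]) -> list[OutcomeBurden]:
    """Read burden rows from CSV (costs in billions USD; case columns optional).

    A row must give either all three case components or none.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise BurdenParseError("empty burden file: no header row")
    missing = [c for c in _BURDEN_COLUMNS[:7] if c not in reader.fieldnames]
    if missing:
        raise BurdenParseError(f"header missing column(s): {', '.join(missing)}")
    rows = []
    for i, raw in enumerate(reader, 1):
        try:
            cost = Triple(
                float(raw["cost_base"]), float(raw["cost_low"]), float(raw["cost_high"])
            )
        except (TypeError, ValueError):
            raise BurdenParseError(f"row {i}: cost columns are not numbers") from None
        case_vals = [raw.get(f"cases_{k}") for k in ("base", "low", "high")]
        present = [v not in (None, "") for v in case_vals]
        if any(present) and not all(present):
            raise BurdenParseError(
                f"row {i}: case counts must give all of base/low/high or none"
            )
        cases = Triple(*map(float, case_vals)) if all(present) else None
        try:
            rows.append(
                OutcomeBurden(
                    chemical_class=raw["chemical_class"],
                    exposure_chemical=raw["exposure_chemical"],
                    life_stage=raw["life_stage"],
                    outcome=raw["outcome"],
                    cost=cost,
                    cases=cases,
                )
            )
        except ValueError as exc:
            raise BurdenParseError(f"row {i}: {exc}") from exc
    if not rows:
        raise BurdenParseError("burden file contains a header but no rows")
    return rows


def write_burden_table(rows: Sequence[OutcomeBurden], target: str | Path | IO[str]) -> None:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_BURDEN_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for r in rows:
        rec = {
            "chemical_class": r.chemical_class,
            "exposure_chemical": r.exposure_chemical,
            "life_stage": r.life_stage,
            "outcome": r.outcome,
            "cost_base": repr(r.cost.base),
            "cost_low": repr(r.cost.low),
            "cost_high": repr(r.cost.high),
            "cases_base": "" if r.cases is None else repr(r.cases.base),
            "cases_low": "" if r.cases is None else repr(r.cases.low),
            "cases_high": "" if r.cases is None else repr(r.cases.high),
        }
        writer.writerow(rec)
    if hasattr(target, "write"):
        target.write(buf.getvalue())
    else:
        Path(target).write_text(buf.getvalue(), encoding="utf-8")


def _rule_from_mapping(doc: Mapping, index: int) -> AttributionRule:
    match = doc.get("match", {}) or {}
    override = doc.get("prf_override")
    prf_override = None
    if override is not None:
        prf_override = PRFTriple(
            base=float(override["base"]),
            low=float(override["low"]),
            high=float(override["high"]),
            chemical_id=str(override.get("chemical_id", "")),
        )
    try:
        return AttributionRule(
            match_class=str(match.get("chemical_class", WILDCARD)),
            match_outcome=str(match.get("outcome", WILDCARD)),
            base_prf_chemical=doc.get("base_prf_chemical"),
            envelope_prf_chemicals=tuple(doc.get("envelope_prf_chemicals", ()) or ()),
            prf_override=prf_override,
        )
    except RuleError as exc:
        raise RuleError(f"rule {index}: {exc}") from exc


def read_rules(source: str | Path | IO[str]) -> list[AttributionRule]:
    """Read an attribution rule list from YAML or JSON (a YAML superset)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, list) or not doc:
        raise RuleError("rules file must contain a nonempty list of rules")
    return [_rule_from_mapping(d, i) for i, d in enumerate(doc, 1)]
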