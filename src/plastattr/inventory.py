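"""Chemical use-share inventories with plastic-relatedness classification.

An inventory (:class:`ChemicalUseProfile`) lists, for one chemical, every
application it is put to, together with the share of total use that the
application accounts for and a classification of whether that application is
fully, partially, or not at all plastic related.  Shares may be expressed as
percentages of total use, as production masses (tons per year), or — when use
data are unavailable and emissions serve as a proxy — as percentages of total
emissions.  All three bases reduce to the same thing after normalization: a
vector of fractions summing to one.

I/O is plain CSV (one row per use category) or an equivalent JSON document.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO

from .errors import InventoryError, ProfileParseError

__all__ = [
    "Basis",
    "PlasticityClass",
    "UseShare",
    "ChemicalUseProfile",
    "normalize_shares",
    "read_profile",
    "write_profile",
]

#: Relative deviation of a percent-basis share sum from 100 beyond which a
#: renormalization warning is emitted (sums inside this band are treated as
#: rounding noise in the source table).
PERCENT_SUM_WARN_TOL = 1.0

_CSV_COLUMNS = (
    "category",
    "share_value",
    "basis",
    "plasticity",
    "partial_fraction_override",
    "note",
)


class Basis(str, Enum):
    """How a use share is expressed in its source."""

    PERCENT = "PERCENT"                    # percent of total use
    MASS = "MASS"                          # tons (or any mass unit) per year
    EMISSIONS_PERCENT = "EMISSIONS_PERCENT"  # percent of total emissions (use proxy)


class PlasticityClass(str, Enum):
    """Plastic-relatedness of one use category.

    FULL: the application fully meets the plastic-related use criteria
    (monomer, plastic additive, processing aid, or surface treatment applied
    to plastics).  PARTIAL: the application meets them sometimes, or the
    evidence is insufficient to say it always does.  NONE: the application
    falls entirely outside the criteria.
    """

    FULL = "FULL"
    PARTIAL = "PARTIAL"
    NONE = "NONE"


def _coerce_enum(value, enum_cls):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(str(value).strip().upper())
    except ValueError:
        raise InventoryError(
            f"unknown {enum_cls.__name__} label {value!r}; "
            f"expected one of {[m.value for m in enum_cls]}"
        ) from None


@dataclass(frozen=True)
class UseShare:
    """One classified row of a use inventory.

    Parameters
    ----------
    category:
        Free-text label of the application (e.g. ``"Polycarbonate plastic"``).
    share_value:
        Nonnegative share in the units of ``basis`` (percent or mass).
    basis:
        How ``share_value`` is expressed; must be uniform within a profile.
    plasticity:
        FULL / PARTIAL / NONE classification of the application.
    partial_fraction_override:
        For PARTIAL rows only: a known plastic-related sub-fraction on [0, 1]
        determined from secondary sources, used identically for the base, low
        and high estimate.  Absent, the configurable partial imputation
        (default 0.50, sensitivity 0.25–0.75) applies.
    note:
        Free-text provenance/comment.
    """

    category: str
    share_value: float
    basis: Basis
    plasticity: PlasticityClass
    partial_fraction_override: float | None = None
    note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "basis", _coerce_enum(self.basis, Basis))
        object.__setattr__(
            self, "plasticity", _coerce_enum(self.plasticity, PlasticityClass)
        )
        object.__setattr__(self, "share_value", float(self.share_value))
        if self.share_value < 0:
            raise InventoryError(
                f"share_value must be nonnegative, got {self.share_value} "
                f"for category {self.category!r}"
            )
        if self.partial_fraction_override is not None:
            if self.plasticity is not PlasticityClass.PARTIAL:
                raise InventoryError(
                    "partial_fraction_override is only meaningful for PARTIAL rows "
                    f"(category {self.category!r} is {self.plasticity.value})"
                )
            p = float(self.partial_fraction_override)
            if not 0.0 <= p <= 1.0:
                raise InventoryError(
                    f"partial_fraction_override must lie in [0, 1], got {p}"
                )
            object.__setattr__(self, "partial_fraction_override", p)


@dataclass(frozen=True)
class ChemicalUseProfile:
    """A chemical's complete classified use inventory on a single basis."""

    chemical_id: str
    shares: tuple[UseShare, ...]
    source_note: str = ""

    def __post_init__(self):
        object.__setattr__(self, "shares", tuple(self.shares))
        if not self.shares:
            raise InventoryError(f"profile {self.chemical_id!r} has no use shares")
        bases = {s.basis for s in self.shares}
        if len(bases) > 1:
            raise InventoryError(
                f"profile {self.chemical_id!r} mixes bases "
                f"{sorted(b.value for b in bases)}; a profile must use one basis"
            )

    @property
    def basis(self) -> Basis:
        return self.shares[0].basis


def normalize_shares(profile: ChemicalUseProfile) -> list[float]:
    """Return the profile's shares as fractions of the total, summing to 1.

    All bases normalize the same way — each share divided by the share sum.
    For percent-like bases whose printed values do not total 100 (source
    rounding, or partial columns such as emissions attributed to one
    compound), the division rescales them; a :class:`UserWarning` is emitted
    when the raw sum deviates from 100 by more than ``PERCENT_SUM_WARN_TOL``.

    Raises
    ------
    InventoryError
        If every share is zero (an empty inventory carries no information).
    """
    values = [s.share_value for s in profile.shares]
    total = sum(values)
    if total <= 0.0:
        raise InventoryError(
            f"profile {profile.chemical_id!r}: all shares are zero — empty inventory"
        )
    if profile.basis in (Basis.PERCENT, Basis.EMISSIONS_PERCENT):
        if abs(total - 100.0) > PERCENT_SUM_WARN_TOL:
            warnings.warn(
                f"profile {profile.chemical_id!r}: percent shares sum to "
                f"{total:g}, not 100; renormalizing to fractions of their sum",
                UserWarning,
                stacklevel=2,
            )
    return [v / total for v in values]


# ---------------------------------------------------------------------------
# I/O


def _parse_share_row(row: dict, index: int) -> UseShare:
    missing = [c for c in _CSV_COLUMNS[:4] if row.get(c) in (None, "")]
    if missing:
        raise ProfileParseError(f"row {index}: missing field(s) {', '.join(missing)}")
    override_raw = row.get("partial_fraction_override")
    override = None
    if override_raw not in (None, ""):
        try:
            override = float(override_raw)
        except (TypeError, ValueError):
            raise ProfileParseError(
                f"row {index}: field partial_fraction_override is not a number: "
                f"{override_raw!r}"
            ) from None
    try:
        share_value = float(row["share_value"])
    except (TypeError, ValueError):
        raise ProfileParseError(
            f"row {index}: field share_value is not a number: {row['share_value']!r}"
        ) from None
    try:
        return UseShare(
            category=str(row["category"]),
            share_value=share_value,
            basis=row["basis"],
            plasticity=row["plasticity"],
            partial_fraction_override=override,
            note=str(row.get("note") or ""),
        )
    except InventoryError as exc:
        raise ProfileParseError(f"row {index}: {exc}") from exc


def read_profile(
    source: str | Path | IO[str],
    fmt: str | None = None,
    chemical_id: str | None = None,
) -> ChemicalUseProfile:
    """Read a :class:`ChemicalUseProfile` from a CSV or JSON file or stream.

    ``fmt`` ("csv" or "json") is inferred from the file suffix when omitted.
    For CSV input the chemical identifier is not part of the format; it is
    taken from ``chemical_id`` or, failing that, the upper-cased file stem.
    Row order is preserved.
    """
    if hasattr(source, "read"):
        text = source.read()
        path = None
    else:
        path = Path(source)
        if fmt is None:
            fmt = path.suffix.lstrip(".").lower()
        text = path.read_text(encoding="utf-8")
    if fmt not in ("csv", "json"):
        raise ProfileParseError(f"unknown profile format {fmt!r}; expected csv or json")

    if fmt == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ProfileParseError(f"invalid JSON profile: {exc}") from exc
        shares = [
            _parse_share_row(dict(row), i) for i, row in enumerate(doc.get("shares", []), 1)
        ]
        if not shares:
            raise ProfileParseError("JSON profile contains no shares")
        cid = chemical_id or doc.get("chemical_id")
        if not cid:
            raise ProfileParseError("JSON profile missing chemical_id")
        return ChemicalUseProfile(
            chemical_id=cid, shares=tuple(shares), source_note=doc.get("source_note", "")
        )

    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise ProfileParseError("empty profile file: no header row")
    missing = [c for c in _CSV_COLUMNS[:4] if c not in reader.fieldnames]
    if missing:
        raise ProfileParseError(f"header missing column(s): {', '.join(missing)}")
    shares = [_parse_share_row(row, i) for i, row in enumerate(reader, 1)]
    if not shares:
        raise ProfileParseError("profile file contains a header but no rows")
    if chemical_id is None:
        if path is None:
            raise ProfileParseError("chemical_id required when reading CSV from a stream")
        chemical_id = path.stem.upper()
    return ChemicalUseProfile(chemical_id=chemical_id, shares=tuple(shares))


def write_profile(
    profile: ChemicalUseProfile,
    target: str | Path | IO[str],
    fmt: str | None = None,
) -> None:
    """Write a profile as CSV or JSON (inverse of :func:`read_profile`).

    JSON is lossless (includes ``chemical_id`` and ``source_note``); CSV
    carries the share rows only.
    """
    if hasattr(target, "write"):
        handle, path = target, None
    else:
        path = Path(target)
        if fmt is None:
            fmt = path.suffix.lstrip(".").lower()
        handle = None
    if fmt not in ("csv", "json"):
        raise InventoryError(f"unknown profile format {fmt!r}; expected csv or json")

    if fmt == "json":
        doc = {
            "chemical_id": profile.chemical_id,
            "source_note": profile.source_note,
            "shares": [
                {
                    "category": s.category,
                    "share_value": s.share_value,
                    "basis": s.basis.value,
                    "plasticity": s.plasticity.value,
                    "partial_fraction_override": s.partial_fraction_override,
                    "note": s.note,
                }
                for s in profile.shares
            ],
        }
        text = json.dumps(doc, indent=2)
        if handle is not None:
            handle.write(text)
        else:
            path.write_text(text, encoding="utf-8")
        return

    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=_CSV_COLUMNS, lineterminator="\n")
    writer.writeheader()
    for s in profile.shares:
        writer.writerow(
            {
                "category": s.category,
                "share_value": repr(s.share_value),
                "basis": s.basis.value,
                "plasticity": s.plasticity.value,
                "partial_fraction_override": ""
                if s.partial_fraction_override is None
                else repr(s.partial_fraction_override),
                "note": s.note,
            }
        )
    if handle is not None:
        handle.write(buf.getvalue())
    else:
        path.write_text(buf.getvalue(), encoding="utf-8")
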