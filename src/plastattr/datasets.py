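"""Bundled reference inputs: the seven classified use inventories, the 2018 US
disease-burden table, and the default attribution rule sets.

Chemicals covered: BPA, DEHP, BBP, DBP (phthalates and bisphenol A), PFOA and
PFOS (PFAS), and PBDE-47 (penta-BDE flame retardant).  The burden table
carries point cost estimates only; the published low/high cost bounds of the
source studies are not publicly tabulated, so sensitivity ranges computed from
this table reflect PRF uncertainty alone.
"""

from __future__ import annotations

from importlib import resources

from .attribution import AttributionRule, OutcomeBurden, read_burden_table, read_rules
from .inventory import ChemicalUseProfile, read_profile
from .prf import DEFAULT_IMPUTATION, PartialImputation, PRFTriple, compute_prf

__all__ = [
    "CHEMICALS",
    "load_profile",
    "load_burden_table",
    "default_rules",
    "printed_rules",
    "reference_prfs",
]

#: Canonical identifiers of the bundled inventories.
CHEMICALS = ("BPA", "DEHP", "BBP", "DBP", "PFOA", "PFOS", "PBDE47")

_DATA = resources.files(__package__) / "data"


def load_profile(chemical_id: str) -> ChemicalUseProfile:
    """Load a bundled use inventory, e.g. ``load_profile("BPA")``.

    Besides the seven canonical inventories, ``"PFOA_PFCA_RAW"`` loads the
    PFOA emission shares before rescaling to the APFO-attributed column
    (percent of *all* PFCA-related emissions; sums to 72, renormalized on
    use).
    """
    stem = chemical_id.lower()
    path = _DATA / f"{stem}.csv"
    if not path.is_file():
        raise FileNotFoundError(f"no bundled inventory for {chemical_id!r}")
    cid = "PFOA" if stem == "pfoa_pfca_raw" else chemical_id.upper()
    with path.open("r", encoding="utf-8") as fh:
        return read_profile(fh, fmt="csv", chemical_id=cid)


def load_burden_table() -> list[OutcomeBurden]:
    """The 2018 US disease-burden table (costs in billions of 2018 USD)."""
    with (_DATA / "burden_us2018.csv").open("r", encoding="utf-8") as fh:
        return read_burden_table(fh)


def default_rules() -> list[AttributionRule]:
    """Attribution rules applying unrounded computed PRF triples."""
    with (_DATA / "rules_default.yaml").open("r", encoding="utf-8") as fh:
        return read_rules(fh)


def printed_rules() -> list[AttributionRule]:
    """Attribution rules applying the published *rounded* PRF triples.

    Use these to reproduce individually printed attributable cells to their
    displayed precision; the default (unrounded) rules are otherwise
    preferable.
    """
    with (_DATA / "rules_printed.yaml").open("r", encoding="utf-8") as fh:
        return read_rules(fh)


def reference_prfs(
    imputation: PartialImputation = DEFAULT_IMPUTATION,
) -> dict[str, PRFTriple]:
    """PRF triples computed from the seven bundled inventories."""
    return {c: compute_prf(load_profile(c), imputation) for c in CHEMICALS}
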