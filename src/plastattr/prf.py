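"""Plastic-related fraction (PRF) estimation.

The PRF of a chemical is the fraction of its total use (or, for emission-proxy
inventories, total emissions) that is plastic related.  It is a
classification-weighted sum over the chemical's normalized use shares

    PRF_k = sum_i f_i * w_{i,k},        k in {base, low, high}

where f_i are the fractions from :func:`plastattr.inventory.normalize_shares`
and w_{i,k} is the plastic weight of row i: 1 for FULL rows, 0 for NONE rows,
and for PARTIAL rows either a known sub-fraction (identical across k) or the
configurable partial imputation — by default half of the application assumed
plastic related, with 25% / 75% bounds for the sensitivity analysis.

Under the model's proportionality assumption (disease burden scales with
exposure, exposure scales with use), the PRF is also the attributable fraction
applied to burden and cost estimates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

from .inventory import ChemicalUseProfile, PlasticityClass, UseShare, normalize_shares

__all__ = ["PartialImputation", "PRFTriple", "plastic_weight", "compute_prf",
           "DEFAULT_IMPUTATION"]

_ORDER_TOL = 1e-9


@dataclass(frozen=True)
class PartialImputation:
    """Plastic-related fraction imputed to unquantifiable PARTIAL uses.

    ``base`` is the main-estimate fraction, ``low``/``high`` the sensitivity
    bounds.  Defaults: half of the application assumed plastic related, with a
    25–75% sensitivity range.
    """

    base: float = 0.50
    low: float = 0.25
    high: float = 0.75

    def __post_init__(self):
        if not 0.0 <= self.low <= self.base <= self.high <= 1.0:
            raise ValueError(
                "partial imputation must satisfy 0 <= low <= base <= high <= 1, "
                f"got base={self.base}, low={self.low}, high={self.high}"
            )


DEFAULT_IMPUTATION = PartialImputation()


@dataclass(frozen=True)
class PRFTriple:
    """Base / low / high plastic-related fractions for one chemical."""

    base: float
    low: float
    high: float
    chemical_id: str = ""

    def __post_init__(self):
        for name in ("base", "low", "high"):
            v = getattr(self, name)
            if not -_ORDER_TOL <= v <= 1.0 + _ORDER_TOL:
                raise ValueError(
                    f"PRF {name} component out of [0, 1]: {v} ({self.chemical_id})"
                )
        if self.low > self.base + _ORDER_TOL or self.base > self.high + _ORDER_TOL:
            raise ValueError(
                "PRF components must satisfy low <= base <= high, got "
                f"({self.base}, {self.low}, {self.high}) for {self.chemical_id!r}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.base, self.low, self.high)


def plastic_weight(
    share: UseShare, imputation: PartialImputation = DEFAULT_IMPUTATION
) -> tuple[float, float, float]:
    """Plastic weight (base, low, high) of a single classified use row.

    FULL rows weigh (1, 1, 1) and NONE rows (0, 0, 0).  PARTIAL rows weigh the
    imputation triple, or a flat ``(p, p, p)`` when a known sub-fraction
    ``partial_fraction_override = p`` was determined from secondary sources
    (the sensitivity bounds exist only for *unquantifiable* partial uses).
    """
    if share.plasticity is PlasticityClass.FULL:
        return (1.0, 1.0, 1.0)
    if share.plasticity is PlasticityClass.NONE:
        return (0.0, 0.0, 0.0)
    if share.partial_fraction_override is not None:
        p = share.partial_fraction_override
        return (p, p, p)
    return (imputation.base, imputation.low, imputation.high)


def compute_prf(
    profile: ChemicalUseProfile, imputation: PartialImputation = DEFAULT_IMPUTATION
) -> PRFTriple:
    """Compute the PRF triple of a chemical from its classified inventory.

    Each component is the dot product of the normalized shares with the
    corresponding plastic weights.  Values are kept unrounded; rounding to a
    reporting precision is the report module's job.
    """
    fractions = normalize_shares(profile)
    base = low = high = 0.0
    for f, share in zip(fractions, profile.shares):
        wb, wl, wh = plastic_weight(share, imputation)
        base += f * wb
        low += f * wl
        high += f * wh
    return PRFTriple(base=base, low=low, high=high, chemical_id=profile.chemical_id)
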