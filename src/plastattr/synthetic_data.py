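"""Synthetic use inventories and burden tables with known ground truth.

The generator emulates the structure of real inputs — a mixture of FULL /
PARTIAL / NONE use shares on any basis, and burden rows with ordered
base/low/high cost triples — while computing the true PRF and the true
attributable table *during generation* with deliberately naive per-element
loops.  That oracle path shares no code with the pipeline proper, so the two
cannot agree by construction; agreement is exact (closed-form arithmetic, no
estimation error).

A single integer seed drives one named pseudorandom stream per call; there is
no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .attribution import (
    AttributableResult,
    AttributableTable,
    AttributionRule,
    OutcomeBurden,
    Triple,
)
from .inventory import Basis, ChemicalUseProfile, PlasticityClass, UseShare
from .prf import DEFAULT_IMPUTATION, PartialImputation, PRFTriple

__all__ = ["GeneratorSpec", "gen_profile", "gen_burden_table", "identity_rules"]

_LIFE_STAGES = ("Prenatal", "Children", "Adults", "Women", "Men")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-data stream.

    ``class_probabilities`` is the (FULL, PARTIAL, NONE) mixture over use
    categories; ``override_probability`` is the chance a PARTIAL row carries a
    known sub-fraction; ``cost_scale`` sets the magnitude of generated cost
    triples (billions USD).
    """

    seed: int = 0
    n_categories: int = 5
    basis: Basis = Basis.PERCENT
    class_probabilities: tuple[float, float, float] = (0.4, 0.3, 0.3)
    override_probability: float = 0.2
    n_outcomes: int = 8
    cost_scale: float = 10.0

    def __post_init__(self):
        object.__setattr__(self, "basis", Basis(self.basis))
        if self.n_categories < 1:
            raise ValueError(f"n_categories must be >= 1, got {self.n_categories}")
        if self.n_outcomes < 1:
            raise ValueError(f"n_outcomes must be >= 1, got {self.n_outcomes}")
        p = self.class_probabilities
        if len(p) != 3 or any(not 0 <= x <= 1 for x in p) or abs(sum(p) - 1) > 1e-9:
            raise ValueError(
                f"class_probabilities must be three fractions summing to 1, got {p}"
            )
        if not 0 <= self.override_probability <= 1:
            raise ValueError("override_probability must lie in [0, 1]")
        if self.cost_scale <= 0:
            raise ValueError("cost_scale must be positive")


def gen_profile(
    spec: GeneratorSpec, imputation: PartialImputation = DEFAULT_IMPUTATION
) -> tuple[ChemicalUseProfile, PRFTriple]:
    """Generate a random classified use inventory and its true PRF triple.

    Shares come from a symmetric Dirichlet split (scaled to percent) for
    percent-like bases, or positive gamma draws for the MASS basis.  The
    returned ``true_prf`` is computed by a direct per-row summation that is
    independent of :func:`plastattr.prf.compute_prf`.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_categories
    if spec.basis is Basis.MASS:
        values = rng.gamma(shape=2.0, scale=50.0, size=n) + 1e-6
    else:
        values = rng.dirichlet(np.ones(n)) * 100.0
    class_order = (PlasticityClass.FULL, PlasticityClass.PARTIAL, PlasticityClass.NONE)
    classes = [
        class_order[i]
        for i in rng.choice(3, size=n, p=list(spec.class_probabilities))
    ]
    shares = []
    for i in range(n):
        override = None
        if classes[i] is PlasticityClass.PARTIAL and rng.random() < spec.override_probability:
            override = float(rng.uniform())
        shares.append(
            UseShare(
                category=f"use_{i}",
                share_value=float(values[i]),
                basis=spec.basis,
                plasticity=classes[i],
                partial_fraction_override=override,
            )
        )
    profile = ChemicalUseProfile(
        chemical_id=f"SYN{spec.seed}",
        shares=tuple(shares),
        source_note="synthetic",
    )

    # Oracle: naive per-row accumulation of share * weight, divided at the end.
    total = 0.0
    acc = {"base": 0.0, "low": 0.0, "high": 0.0}
    for s in shares:
        total = total + s.share_value
    for s in shares:
        if s.plasticity is PlasticityClass.FULL:
            w = {"base": 1.0, "low": 1.0, "high": 1.0}
        elif s.plasticity is PlasticityClass.NONE:
            w = {"base": 0.0, "low": 0.0, "high": 0.0}
        elif s.partial_fraction_override is not None:
            w = {
                "base": s.partial_fraction_override,
                "low": s.partial_fraction_override,
                "high": s.partial_fraction_override,
            }
        else:
            w = {"base": imputation.base, "low": imputation.low, "high": imputation.high}
        for k in acc:
            acc[k] = acc[k] + (s.share_value / total) * w[k]
    true_prf = PRFTriple(
        base=acc["base"], low=acc["low"], high=acc["high"], chemical_id=profile.chemical_id
    )
    return profile, true_prf


def identity_rules(prfs: Mapping[str, PRFTriple]) -> list[AttributionRule]:
    """One rule per chemical, mapping rows of class ``c`` to chemical ``c``."""
    return [
        AttributionRule(
            match_class=c, base_prf_chemical=c, envelope_prf_chemicals=(c,)
        )
        for c in prfs
    ]


def gen_burden_table(
    spec: GeneratorSpec, prfs: Mapping[str, PRFTriple]
) -> tuple[list[OutcomeBurden], AttributableTable]:
    """Generate burden rows and the true attributable table under ``prfs``.

    Each row is labelled with the chemical whose PRF applies (its
    ``chemical_class`` equals the chemical id, matching
    :func:`identity_rules`).  Cost triples are three positive draws sorted
    into (low, base, high); about half the rows carry case counts.  The
    ground-truth table is accumulated with plain componentwise loops.
    """
    if not prfs:
        raise ValueError("gen_burden_table requires at least one PRF triple")
    rng = np.random.default_rng(spec.seed)
    chemicals = sorted(prfs)
    rows: list[OutcomeBurden] = []
    for i in range(spec.n_outcomes):
        chem = chemicals[int(rng.integers(len(chemicals)))]
        draws = sorted(float(x) * spec.cost_scale for x in rng.uniform(0.01, 1.0, size=3))
        cost = Triple(base=draws[1], low=draws[0], high=draws[2])
        cases = None
        if rng.random() < 0.5:
            c = sorted(int(x) for x in rng.integers(1, 100000, size=3))
            cases = Triple(base=float(c[1]), low=float(c[0]), high=float(c[2]))
        rows.append(
            OutcomeBurden(
                chemical_class=chem,
                exposure_chemical=chem,
                life_stage=str(rng.choice(_LIFE_STAGES)),
                outcome=f"outcome_{i}",
                cost=cost,
                cases=cases,
            )
        )

    # Oracle: naive componentwise products and running sums.
    truth_results = []
    subtotals: dict[str, list[float]] = {}
    grand = [0.0, 0.0, 0.0]
    for row in rows:
        prf = prfs[row.chemical_class]
        prf_parts = (prf.base, prf.low, prf.high)
        cost_parts = []
        for k in range(3):
            cost_parts.append(row.cost[k] * prf_parts[k])
        cases_t = None
        if row.cases is not None:
            cases_parts = []
            for k in range(3):
                cases_parts.append(row.cases[k] * prf_parts[k])
            cases_t = Triple(*cases_parts)
        truth_results.append(
            AttributableResult(
                burden=row,
                applied_prf=prf,
                attributable_cost=Triple(*cost_parts),
                attributable_cases=cases_t,
            )
        )
        acc = subtotals.setdefault(row.chemical_class, [0.0, 0.0, 0.0])
        for k in range(3):
            acc[k] = acc[k] + cost_parts[k]
            grand[k] = grand[k] + cost_parts[k]
    truth = AttributableTable(
        results=tuple(truth_results),
        class_subtotals={c: Triple(*acc) for c, acc in subtotals.items()},
        grand_total=Triple(*grand),
    )
    return rows, truth
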