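# Methods

## Model and assumptions

`plastattr` implements a three-point (base / low / high) attribution model for
the plastic-related share of chemical disease burden.

**Plastic-related fraction (PRF).** A chemical's inventory lists its use
categories with shares on one basis — percent of total use, production mass
per year, or (when use data are unavailable, as for PFOA) percent of total
emissions as a proxy. An application counts as plastic related when it acts as
a monomer, a plastic additive, a processing aid, or a surface treatment
applied to plastics. Each category is classified FULL, PARTIAL, or NONE
against these criteria; classification is *input data*, not computed — it is a
qualitative literature judgment that the package deliberately does not try to
automate. After normalizing shares to fractions f that sum to one, the PRF is
the share-weighted sum PRF_k = Σ f_i · w_{i,k} over k ∈ {base, low, high},
with weights 1 (FULL), 0 (NONE), and for PARTIAL rows either a known
sub-fraction (applied identically to all three components) or the partial
imputation.

**Partial imputation.** When a partially plastic-related use cannot be further
quantified, half of it is assumed plastic related in the base case, with 25%
and 75% low/high bounds in the sensitivity analysis. The triple is
configurable per run (`PartialImputation`; CLI flags `--partial-base/low/high`)
and defaults to (0.50, 0.25, 0.75). PRF components are dimensionless fractions
on [0, 1] and always satisfy low ≤ base ≤ high.

**Attribution.** The only model linking PRF to burden is proportionality:
disease burden is proportional to exposure and exposure to use, so
attributable cost (and cases, when present) is the componentwise product of
the burden triple with the applied PRF triple. The sensitivity pairing is
fixed multiway — lowest PRF bound × lowest cost bound, highest × highest,
never crossed. Uncertainty is interval propagation of these three points only;
no probabilistic (Monte-Carlo) propagation is attempted, because probabilities
of causation are not available for all outcomes considered.

**Attribution rules.** Burden rows are matched on (chemical class, outcome)
with wildcards; the most specific rule wins and ambiguity is an error. A rule
names the base-PRF chemical and an envelope of chemicals whose min-low /
max-high bounds form the applied sensitivity range — PFAS outcomes are costed
from PFOA exposure but take their low bound from PFOS, whose plastic-related
share (31.7%) is far below PFOA's (93%). A rule may instead carry an explicit
override triple; the bundled phthalate-infertility rule does (see
*Known inconsistencies*).

**Aggregation** is componentwise summation per chemical class and overall, so
class low/high totals are all-low / all-high combinations, consistent with the
multiway convention.

## Bundled reference inputs

Seven classified inventories (BPA, DEHP, BBP, DBP, PFOA, PFOS, PBDE-47) and a
2018 US cost-of-illness table (22 outcome rows across PBDE, phthalate, BPA and
PFAS classes, in billions of 2018 USD) ship as CSV under
`src/plastattr/data/`. Notable encoding choices:

- **DBP and PFOS** are mass-basis (tons/metric tons per year); their percent
  columns fall out of normalization (e.g. 5900/8280 = 71.26%).
- **PFOA** uses emission shares as a use proxy. The canonical inventory stores
  the rescaled APFO-attributed column (79.2 / 13.8 / 6.9) plus a 0.1% rounding
  residual classified NONE, so the column keeps its stated denominator of 100
  and the derived triple is exactly 93% (89.55–96.45%) — the rescaled shares
  as printed sum to 99.9 only because each was rounded to one decimal. The
  pre-rescaling column (57 / 10 / 5, summing to 72% of all PFCA-related
  emissions) ships as `PFOA_PFCA_RAW` and renormalizes to the same 93% base.
- **PBDE-47**'s flexible-polyurethane-foam share is reported as a 95–98%
  range; the inventory stores the 96.5% midpoint. The published sensitivity
  bounds (97.38–99.13%) arise from varying the partial imputation at that
  fixed split, not from the share range, so the range itself does not enter
  the analysis.
- **Burden table**: the source studies publish point cost estimates; their
  low/high cost bounds are not publicly tabulated, so the bundled table sets
  cost_low = cost_high = cost_base and pipeline ranges computed from it
  reflect PRF uncertainty only. Case counts are likewise unpublished at the
  source level and omitted; rows without case triples simply produce no case
  outputs.

Two rule sets ship. `rules_default.yaml` applies unrounded computed PRF
triples. `rules_printed.yaml` applies the *rounded* triples as printed in the
published attribution table (98/97/99 for PBDE, 98/96/99 for DEHP and BPA,
93/16/96 for PFAS, 100/71/100 for infertility); use it to reproduce
individually printed attributable cells to their displayed precision, e.g.
$1.04B × 0.98 = $1.02B for BPA.

## Known inconsistencies in the reference values

These are carried, not patched:

- The published phthalate class subtotal ($66.7B) is not the sum of its own
  printed outcome rows (≈$67.5B at the printed PRFs); tests assert the
  recomputed sum. Consequently the published grand total ($249B) is exactly
  the sum of the published *rounded* class subtotals (159 + 66.7 + 1.02 +
  22.4 = 249.12 → $249B) and is reproduced as such, while an end-to-end
  unrounded run gives ≈$251B.
- The infertility PRF 100% (71–100%) matches no triple computable from any
  bundled inventory (the named chemicals compute to 100/100/100 and
  85/79/91); it ships verbatim as an explicit rule override.
- For PFOS, the running text reports 48% (24–72%) but the use table totals
  31.7% (15.8–47.5%); the table value is used, consistent with the 16% low
  bound applied to PFAS outcomes downstream.
- DEHP is summarized in one place as 98% (96–99%) and derived in another as
  98.5% (98–99%); the derivation (0.97 + 0.03 × imputation) is what the
  inventory reproduces.

## Numerical choices

- All PRF and attribution arithmetic is unrounded `float64`; rounding is
  presentation-only, in the report module.
- Display rounding is round-half-even (banker's rounding) at 3 significant
  figures for costs and ≤2 decimals for percents, via `decimal`. Published
  values appear to use half-up in places (99.125 → 99.13); tests therefore
  compare numerics within half a unit of printed precision rather than
  matching strings.
- Costs below $0.1 billion display in millions.
- Normalization divides by the share sum on every basis; percent-like columns
  whose raw sum deviates from 100 by more than 1 unit trigger a warning while
  still renormalizing (the PFOA raw column, summing to 72, is the intended
  use of this path). An all-zero inventory is an error, as is a negative
  share, a mixed-basis profile, or an override on a non-PARTIAL row.
- Triple orderings (low ≤ base ≤ high) are validated with 1e-9 slack to
  absorb float round-off from CSV parsing.

## Synthetic data and what the tests show

`GeneratorSpec`/`gen_profile`/`gen_burden_table` produce seeded random
inventories (Dirichlet percent splits or gamma-distributed masses; FULL /
PARTIAL / NONE drawn from a configurable mixture; occasional known
sub-fractions) and burden tables (three sorted positive cost draws per row).
Ground truth is computed during generation by deliberately naive per-element
loops that share no code with the pipeline, so implementation and oracle
cannot agree through a shared bug; because the model is closed-form
arithmetic, recovery is exact (≤1e-12, typically 0). One `numpy` Generator
seeded per call is the only randomness; identical seeds give byte-identical
serialized output.

The generator emulates the *structure* of real inputs — share mixtures,
classification, ordered cost triples — not realistic chemical-market share
distributions or correlations between outcome costs. Passing recovery tests
therefore demonstrates arithmetic correctness of the pipeline, not the
validity of any real-world classification or cost estimate.

Problem sizes used in the default suite and acceptance script (≤9 categories,
≤12 outcomes, 1000 profile seeds, 200 table seeds) were chosen as comfortably
exhaustive for closed-form arithmetic of this kind; the whole suite runs in a
few seconds.

## Limitations

- Attributable fractions ride entirely on the input classification and share
  data; the package validates and propagates them but cannot audit them.
- Interval propagation has no distributional interpretation: the low/high
  totals are all-low/all-high scenarios, not confidence bounds.
- No discounting, inflation adjustment, or alternative costing (e.g.
  value-of-statistical-life) is implemented; costs pass through on the scale
  given.
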