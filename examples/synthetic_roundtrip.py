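"""Exact parameter recovery on synthetic data.

Generates a random classified inventory and burden table whose true PRF and
attributable totals are computed during generation by an independent naive
loop, then shows the pipeline recovering them to machine precision — the
attribution model is closed-form arithmetic, so recovery is exact.
"""

from plastattr import (
    GeneratorSpec,
    attribute_table,
    compute_prf,
    gen_burden_table,
    gen_profile,
    identity_rules,
)

spec = GeneratorSpec(seed=42, n_categories=6, n_outcomes=5)
profile, true_prf = gen_profile(spec)
computed = compute_prf(profile)
print(f"true PRF:      {true_prf.as_tuple()}")
print(f"computed PRF:  {computed.as_tuple()}")
print(f"max abs error: {max(abs(a - b) for a, b in zip(true_prf.as_tuple(), computed.as_tuple())):.2e}")

prf_map = {true_prf.chemical_id: true_prf}
rows, truth = gen_burden_table(spec, prf_map)
table = attribute_table(rows, identity_rules(prf_map), prf_map)
print(f"\ntrue grand total:     {tuple(truth.grand_total)}")
print(f"pipeline grand total: {tuple(table.grand_total)}")
print(
    "\nAgreement at ~1e-16 confirms the pipeline implements exactly the"
    "\nshare-weighted-sum and componentwise-product model the generator encodes."
)
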