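"""Sensitivity-envelope substitution across chemicals.

PFAS disease-burden estimates are costed from PFOA exposure, but PFOS — with
a far smaller plastic-related share — is the sensitivity alternative.  The
applied PRF therefore takes its base from PFOA and its bounds from the
min/max over both chemicals, yielding the wide published envelope.
"""

from plastattr import compute_prf, datasets, format_percent, resolve_prf

prfs = datasets.reference_prfs()
for chem in ("PFOA", "PFOS"):
    t = prfs[chem]
    print(f"{chem}: {format_percent(t.base)} "
          f"({format_percent(t.low)} - {format_percent(t.high)})")

row = next(r for r in datasets.load_burden_table() if r.outcome == "Low birth weight")
applied = resolve_prf(row, datasets.default_rules(), prfs)
print(
    f"\nApplied to the PFAS '{row.outcome}' row: {format_percent(applied.base)} "
    f"({format_percent(applied.low)} - {format_percent(applied.high)})"
)
print(
    "\nThe base case attributes 93% of the burden to plastics (PFOA), but if"
    "\nPFOS drove the exposure the plastic-related share could be as low as"
    "\n~16% - hence the wide sensitivity range on PFAS attributable costs."
)
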