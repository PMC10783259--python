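# Default chemical -> outcome attribution rules.
#
# Most-specific rule wins. The phthalate infertility row carries an explicit
# published override triple (its 71% low bound matches no computed chemical
# triple; see docs/methods.md). PFAS outcomes take the PFOA base PRF with a
# PFOA+PFOS sensitivity envelope.
- match: {chemical_class: PHTHALATE, outcome: Male infertility}
  prf_override: {base: 1.00, low: 0.71, high: 1.00, chemical_id: BBP and DBP}
- match: {chemical_class: PBDE}
  base_prf_chemical: PBDE47
  envelope_prf_chemicals: [PBDE47]
- match: {chemical_class: PHTHALATE}
  base_prf_chemical: DEHP
  envelope_prf_chemicals: [DEHP]
- match: {chemical_class: BPA}
  base_prf_chemical: BPA
  envelope_prf_chemicals: [BPA]
- match: {chemical_class: PFAS}
  base_prf_chemical: PFOA
  envelope_prf_chemicals: [PFOA, PFOS]
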