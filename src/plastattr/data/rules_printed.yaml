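# Rounded-PRF rule set: every rule applies the PRF triple exactly as printed
# in the published attribution table (e.g. 98%/96%/99% for BPA instead of the
# unrounded 97.5%/96.25%/98.75%), so individually printed attributable cells
# can be reproduced to their displayed precision.
- match: {chemical_class: PHTHALATE, outcome: Male infertility}
  prf_override: {base: 1.00, low: 0.71, high: 1.00, chemical_id: BBP and DBP}
- match: {chemical_class: PBDE}
  prf_override: {base: 0.98, low: 0.97, high: 0.99, chemical_id: PBDE47}
- match: {chemical_class: PHTHALATE}
  prf_override: {base: 0.98, low: 0.96, high: 0.99, chemical_id: DEHP}
- match: {chemical_class: BPA}
  prf_override: {base: 0.98, low: 0.96, high: 0.99, chemical_id: BPA}
- match: {chemical_class: PFAS}
  prf_override: {base: 0.93, low: 0.16, high: 0.96, chemical_id: PFOA}
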