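category,share_value,basis,plasticity,partial_fraction_override,note
Polycarbonate plastic,65,PERCENT,FULL,,All plastic related
Epoxy resins,30,PERCENT,FULL,,All plastic related
Other,5,PERCENT,PARTIAL,,"Stabilizer and antioxidant in PVC production; precursor of the flame retardant TBBPA, which is added to plastics but also paper and textiles"
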