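category,share_value,basis,plasticity,partial_fraction_override,note
PVC flooring (sheet and tile),40,PERCENT,FULL,,All plastic related
PVAc-based caulks and sealants,35,PERCENT,FULL,,All plastic related
PVAc-based adhesives,25,PERCENT,FULL,,All plastic related
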