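category,share_value,basis,plasticity,partial_fraction_override,note
Plasticizer in polymer (primarily PVC),97,PERCENT,FULL,,All plastic related
Other,3,PERCENT,PARTIAL,,"Adhesives and sealants, lacquers and paints, printing inks, rubber, ceramics, dielectric fluid in capacitors"
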