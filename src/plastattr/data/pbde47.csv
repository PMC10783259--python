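category,share_value,basis,plasticity,partial_fraction_override,note
Manufacture of FPUF,96.5,PERCENT,FULL,,"All plastic related; midpoint of the 95-98% range reported for flexible polyurethane foam, chiefly furniture"
"Commercial adhesive products, other uses",3.5,PERCENT,PARTIAL,,Partially plastic related
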