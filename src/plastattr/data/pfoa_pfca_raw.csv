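category,share_value,basis,plasticity,partial_fraction_override,note
APFO used in fluoropolymer manufacture,57,EMISSIONS_PERCENT,FULL,,Percent of all PFCA-related emissions before rescaling to the APFO-attributed share
APFO manufacture,10,EMISSIONS_PERCENT,PARTIAL,,
APFO for fluoropolymer dispersions,5,EMISSIONS_PERCENT,FULL,,
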