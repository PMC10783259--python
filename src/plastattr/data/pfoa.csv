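category,share_value,basis,plasticity,partial_fraction_override,note
APFO used in fluoropolymer manufacture,79.2,EMISSIONS_PERCENT,FULL,,All plastic related; emissions share used as a use proxy
APFO manufacture,13.8,EMISSIONS_PERCENT,PARTIAL,,Partially plastic related (includes nonplastic emissions such as AFFF applications)
APFO for fluoropolymer dispersions,6.9,EMISSIONS_PERCENT,FULL,,All plastic related
Rounding residual of rescaled source shares,0.1,EMISSIONS_PERCENT,NONE,,Keeps the published rescaled column on its stated denominator of 100; not attributable to any listed source
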