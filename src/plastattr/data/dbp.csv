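category,share_value,basis,plasticity,partial_fraction_override,note
Polymer formulation and processing,5900,MASS,FULL,,"All plastic related: flooring, garden hoses, automotive applications, fiberglass; tons per year in source"
Paints (nitrocellulose lacquers),160,MASS,FULL,,Nitrocellulose lacquers are polymeric
Adhesives,1890,MASS,PARTIAL,,"Adhesives in paper and packaging, construction, automotive; typically PVA based but not conclusively quantifiable"
Grouting agents,80,MASS,PARTIAL,,Construction work; typically PUR based but not conclusively quantifiable
"Other, nonpolymeric",250,MASS,NONE,,"Solvent for oil-soluble dyes, insecticides, peroxides and other organics"
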