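category,share_value,basis,plasticity,partial_fraction_override,note
Surface treatments,2160,MASS,PARTIAL,,"Textile mills, leather, carpet, apparel, upholstery, automobile interiors; synthetic-textile share not exactly quantifiable; metric tons in source"
Paper protection,1490,MASS,NONE,,"Food and nonfood paper applications that do not include a plastic layer"
Firefighting foams,151,MASS,NONE,,Not plastic related
Other performance chemicals,680,MASS,PARTIAL,,"Floor polishes, coating additives (often polymeric), plus nonpolymeric surfactants, cleaners, insecticides"
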