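chemical_class,exposure_chemical,life_stage,outcome,cost_base,cost_low,cost_high,cases_base,cases_low,cases_high
PBDE,PBDE47,Prenatal,IQ points loss and intellectual disability,162,162,162,,,
PBDE,PBDE47,Prenatal,Cryptorchidism,0.0357,0.0357,0.0357,,,
PBDE,PBDE47,Prenatal,Testicular cancer,0.081,0.081,0.081,,,
PHTHALATE,DEHP,Women,Obesity,1.95,1.95,1.95,,,
PHTHALATE,DEHP,Women,Type 2 diabetes,0.259,0.259,0.259,,,
PHTHALATE,DEHP,Women,Endometriosis,39.7,39.7,39.7,,,
PHTHALATE,DEHP,Adults,Cardiovascular mortality,23.8,23.8,23.8,,,
PHTHALATE,BBP and DBP,Men,Male infertility,3.14,3.14,3.14,,,
BPA,BPA,Prenatal,Childhood obesity,1.04,1.04,1.04,,,
PFAS,PFOA,Prenatal,Low birth weight,1.42,1.42,1.42,,,
PFAS,PFOA,Prenatal,Childhood obesity,2.65,2.65,2.65,,,
PFAS,PFOA,Children,Pneumonia,0.00149,0.00149,0.00149,,,
PFAS,PFOA,Pregnant people,Gestational diabetes,0.414,0.414,0.414,,,
PFAS,PFOA,Adults,Obesity,17.0,17.0,17.0,,,
PFAS,PFOA,Adults,Kidney cancer,0.180,0.180,0.180,,,
PFAS,PFOA,Adults,Couple infertility,0.0376,0.0376,0.0376,,,
PFAS,PFOA,Women,Hypothyroidism,1.26,1.26,1.26,,,
PFAS,PFOA,Women,Type 2 diabetes,0.140,0.140,0.140,,,
PFAS,PFOA,Women,Endometriosis,0.397,0.397,0.397,,,
PFAS,PFOA,Women,Polycystic ovary syndrome,0.0105,0.0105,0.0105,,,
PFAS,PFOA,Women,Breast cancer,0.555,0.555,0.555,,,
PFAS,PFOA,Men,Testicular cancer,0.00685,0.00685,0.00685,,,
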