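code_system,code_prefix,category,tier
ICD10,J13,pneumonia,1
ICD10,J14,pneumonia,1
ICD10,J15,pneumonia,1
ICD10,J16,pneumonia,1
ICD10,J18,pneumonia,1
ICD10,N10,urinary_tract_infection,1
ICD10,N30,urinary_tract_infection,1
ICD10,N390,urinary_tract_infection,1
ICD10,L01,skin_soft_tissue_infection,1
ICD10,L02,skin_soft_tissue_infection,1
ICD10,L03,skin_soft_tissue_infection,1
ICD10,L08,skin_soft_tissue_infection,1
ICD10,A46,skin_soft_tissue_infection,1
ICD10,A5,sexually_transmitted_infection,1
ICD10,A40,other_tier1_bacterial_infection,1
ICD10,A41,other_tier1_bacterial_infection,1
ICD10,G00,other_tier1_bacterial_infection,1
ICD10,M86,other_tier1_bacterial_infection,1
ICD10,I33,other_tier1_bacterial_infection,1
ICD10,H66,acute_otitis_media,2
ICD10,J01,acute_sinusitis,2
ICD10,J32,acute_sinusitis,2
ICD10,J02,acute_pharyngitis,2
ICD10,J03,acute_tonsillitis,2
ICD10,J40,copd,2
ICD10,J41,copd,2
ICD10,J42,copd,2
ICD10,J44,copd,2
ICD10,A0,infectious_gastroenteritis,2
ICD10,N70,pelvic_inflammatory_disease,2
ICD10,N71,pelvic_inflammatory_disease,2
ICD10,N72,pelvic_inflammatory_disease,2
ICD10,N73,pelvic_inflammatory_disease,2
ICD10,J04,other_respiratory_infection,2
ICD10,J05,other_respiratory_infection,2
ICD10,J36,other_respiratory_infection,2
ICD10,A37,other_tier2_infection,2
ICD10,A38,other_tier2_infection,2
ICD10,K35,other_tier2_infection,2
ICD10,K57,other_tier2_infection,2
ICD10,K81,other_tier2_infection,2
ICD10,L70,other_tier2_infection,2
ICD10,H60,other_tier2_infection,2
ICD10,N34,other_tier2_infection,2
ICD10,J00,viral_upper_respiratory_infection,3
ICD10,J06,viral_upper_respiratory_infection,3
ICD10,J20,acute_bronchitis,3
ICD10,J21,acute_bronchitis,3
ICD10,J09,influenza,3
ICD10,J10,influenza,3
ICD10,J11,influenza,3
ICD10,R50,unspecific_fever,3
ICD10,J45,asthma,3
ICD10,B34,other_viral_infection,3
ICD10,B0,other_viral_infection,3
ICD10,K52,non_infectious_gastroenteritis,3
ICD10,R1,digestive_symptoms,3
ICD10,K,digestive_noninfectious,3
ICD10,I,cardiovascular_disease,3
ICD10,E,endocrine_metabolic,3
ICD10,M,musculoskeletal_disease,3
ICD10,L,dermatologic_noninfectious,3
ICD10,N,genitourinary_noninfectious,3
ICD10,R,symptoms_signs_other,3
ICD10,A,other_noninfectious,3
ICD10,B,other_noninfectious,3
ICD10,C,other_noninfectious,3
ICD10,D,other_noninfectious,3
ICD10,F,other_noninfectious,3
ICD10,G,other_noninfectious,3
ICD10,H,other_noninfectious,3
ICD10,J,other_noninfectious,3
ICD10,O,other_noninfectious,3
ICD10,P,other_noninfectious,3
ICD10,Q,other_noninfectious,3
ICD10,S,other_noninfectious,3
ICD10,T,other_noninfectious,3
ICD10,U,other_noninfectious,3
ICD10,V,other_noninfectious,3
ICD10,W,other_noninfectious,3
ICD10,X,other_noninfectious,3
ICD10,Y,other_noninfectious,3
ICD10,Z,other_noninfectious,3
TCM,ZF,tcm_toxin_syndrome,1
TCM,ZA,tcm_heat_syndrome,2
TCM,ZB,tcm_heat_syndrome,2
TCM,ZC,tcm_exterior_syndrome,3
TCM,ZD,tcm_exterior_syndrome,3
TCM,ZE,tcm_exterior_syndrome,3
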