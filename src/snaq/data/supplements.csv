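id,energy_kj,iron_mg,calcium_mg,folate_dfe_ug,iodine_ug,zinc_mg,folic_acid_ug
prenatal_multivitamin,0,60,125,0,220,11,800
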