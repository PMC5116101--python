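group,energy_kj,iron_mg,calcium_mg,folate_dfe_ug,iodine_ug,zinc_mg
grains,500,1.0,15,30,4,0.7
vegetables,200,0.7,25,40,1.5,0.25
fruit,350,0.3,15,20,1,0.1
meat,550,1.2,30,15,8,2.5
dairy,550,0.1,300,10,30,0.6
fats_oils,250,0.1,2,1,0.3,0.02
discretionary,600,0.3,20,5,2,0.2
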