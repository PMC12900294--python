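ingredient,moisture,crude_protein,crude_lipid,crude_ash,nucleic_acids,crude_carbohydrate
egg_yolk_powder,3.0,33.0,59.0,3.6,0.0,4.4
skimmed_milk_powder,4.0,36.0,1.0,8.2,0.0,54.8
yeast_extract,5.0,55.0,0.5,12.0,12.0,20.5
soy_peptide,6.0,88.0,0.5,6.5,0.0,5.0
casein_na,6.0,92.0,1.0,4.5,0.0,2.5
cpsp,5.0,85.0,9.0,6.0,0.0,0.0
fish_oil,0.5,0.0,99.5,0.3,0.0,0.2
vitamin_mix,3.0,0.0,1.0,24.0,0.0,75.0
taurine,0.5,70.0,0.0,0.5,0.0,29.5
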