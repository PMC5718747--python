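# Characteristic energies of the built-in tissues: photoelectric/Compton crossover Epe,
# Compton/pair-production crossover Epp, and buildup-peak energy Epeak (published reference values)
tissue,Epe_MeV,Epp_MeV,Epeak_MeV
adipose_tissue,0.024,30,0.1
blood,0.029,26,0.1
cortical_bone,0.055,18,0.2
brain,0.028,26,0.1
breast_tissue,0.026,28,0.1
eye_lens,0.027,26,0.1
lung_tissue,0.029,26,0.1
skeletal_muscle,0.028,26,0.1
ovary,0.028,26,0.1
testis,0.028,26,0.1
soft_tissue,0.028,26,0.1
soft_tissue4,0.027,26,0.1
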