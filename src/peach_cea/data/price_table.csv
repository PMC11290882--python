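canonical_name,dose_value,dose_unit,unit_price_gbp,tier
amoxicillin,250,mg,0.03,primary
amoxicillin,500,mg,0.05,primary
amoxicillin,500,mg,0.18,indicative
amikacin,500,mg,3.80,indicative
azithromycin,250,mg,0.32,primary
azithromycin,500,mg,0.55,primary
benzylpenicillin,600,mg,0.68,primary
benzylpenicillin,1200,mg,1.25,primary
cefalexin,250,mg,0.04,primary
cefalexin,500,mg,0.06,primary
ceftriaxone,1000,mg,0.92,primary
ceftriaxone,2000,mg,1.75,primary
cefuroxime,250,mg,0.22,primary
cefuroxime,750,mg,0.85,primary
cefuroxime,1500,mg,1.52,indicative
ciprofloxacin,250,mg,0.04,primary
ciprofloxacin,500,mg,0.06,primary
clarithromycin,250,mg,0.12,primary
clarithromycin,500,mg,0.21,primary
clindamycin,150,mg,0.35,primary
clindamycin,300,mg,0.62,indicative
co-amoxiclav,375,mg,0.12,primary
co-amoxiclav,625,mg,0.16,primary
co-amoxiclav,1200,mg,0.98,primary
co-trimoxazole,480,mg,0.18,primary
co-trimoxazole,960,mg,0.29,primary
doxycycline,50,mg,0.05,primary
doxycycline,100,mg,0.07,primary
ertapenem,1000,mg,31.50,indicative
erythromycin,250,mg,0.14,primary
erythromycin,500,mg,0.24,primary
flucloxacillin,250,mg,0.05,primary
flucloxacillin,500,mg,0.08,primary
flucloxacillin,1000,mg,1.10,indicative
gentamicin,80,mg,1.48,primary
gentamicin,400,mg,3.25,indicative
levofloxacin,250,mg,0.11,primary
levofloxacin,500,mg,0.17,primary
linezolid,600,mg,2.45,indicative
meropenem,500,mg,2.90,primary
meropenem,1000,mg,4.85,primary
metronidazole,200,mg,0.05,primary
metronidazole,400,mg,0.07,primary
metronidazole,500,mg,0.95,primary
nitrofurantoin,50,mg,0.23,primary
nitrofurantoin,100,mg,0.37,primary
piperacillin-tazobactam,2250,mg,1.95,primary
piperacillin-tazobactam,4500,mg,2.45,primary
teicoplanin,200,mg,4.10,indicative
teicoplanin,400,mg,7.60,indicative
temocillin,1000,mg,24.80,indicative
trimethoprim,100,mg,0.04,primary
trimethoprim,200,mg,0.05,primary
vancomycin,500,mg,2.60,primary
vancomycin,1000,mg,4.30,primary
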