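pattern,canonical,action
^paracetamol$,,block
^ibuprofen$,,block
^aspirin$,,block
^dexamethasone$,,block
^remdesivir$,,block
^oseltamivir$,,block
^enoxaparin$,,block
^dalteparin$,,block
^omeprazole$,,block
^lansoprazole$,,block
^salbutamol$,,block
^prednisolone$,,block
^morphine$,,block
^furosemide$,,block
^atorvastatin$,,block
^insulin$,,block
^hydrocortisone$,,block
^codeine$,,block
^tocilizumab$,,block
^amoxicillin$,amoxicillin,map
^amikacin$,amikacin,map
^azithromycin$,azithromycin,map
^benzylpenicillin$,benzylpenicillin,map
^cefalexin$,cefalexin,map
^ceftriaxone$,ceftriaxone,map
^cefuroxime$,cefuroxime,map
^ciprofloxacin$,ciprofloxacin,map
^clarithromycin$,clarithromycin,map
^clindamycin$,clindamycin,map
^co-amoxiclav$,co-amoxiclav,map
^co-trimoxazole$,co-trimoxazole,map
^doxycycline$,doxycycline,map
^ertapenem$,ertapenem,map
^erythromycin$,erythromycin,map
^flucloxacillin$,flucloxacillin,map
^gentamicin$,gentamicin,map
^levofloxacin$,levofloxacin,map
^linezolid$,linezolid,map
^meropenem$,meropenem,map
^metronidazole$,metronidazole,map
^nitrofurantoin$,nitrofurantoin,map
^piperacillin-tazobactam$,piperacillin-tazobactam,map
^teicoplanin$,teicoplanin,map
^temocillin$,temocillin,map
^trimethoprim$,trimethoprim,map
^vancomycin$,vancomycin,map
^co-?amox$,co-amoxiclav,map
^augmentin$,co-amoxiclav,map
^amox$,amoxicillin,map
^tazocin$,piperacillin-tazobactam,map
^tazo$,piperacillin-tazobactam,map
^pip-?taz$,piperacillin-tazobactam,map
^piperacillin[ /+-]?tazobactam$,piperacillin-tazobactam,map
^fluclox$,flucloxacillin,map
^cipro$,ciprofloxacin,map
^clari$,clarithromycin,map
^metro$,metronidazole,map
^vanc$,vancomycin,map
^gent(a)?$,gentamicin,map
^dox(y)?$,doxycycline,map
^azithro$,azithromycin,map
^benpen$,benzylpenicillin,map
^septrin$,co-trimoxazole,map
^mero$,meropenem,map
^teic$,teicoplanin,map
^erythro$,erythromycin,map
^trimeth$,trimethoprim,map
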