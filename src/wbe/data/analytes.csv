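atc_code,name,drug_class,adq_g,excreted_fraction,loq_ng_per_l
J01FA10,Azithromycin,Macrolide antibiotic,0.5,0.85,1
J01DD01,Cefotaxime,Third-generation cephalosporin antibiotic,4,0.85,10
J01MA02,Ciprofloxacin,Fluoroquinolone antibiotic,0.8,1.00,5
J01FA09,Clarithromycin,Macrolide antibiotic,0.5,0.55,4
J01AA02,Doxycycline,Tetracycline antibiotic,0.1,0.80,1
J01FA01,Erythromycin,Macrolide antibiotic,1,1.00,4
J01MA06,Norfloxacin,Fluoroquinolone antibiotic,0.8,0.90,1
J01MA01,Ofloxacin,Fluoroquinolone antibiotic,0.4,0.98,4
J01AA06,Oxytetracycline,Tetracycline antibiotic,1,0.35,4
J01EC01,Sulfamethoxazole,Sulfonamide antibiotic,0.8,1.00,2
J01EA01,Trimethoprim,Dihydrofolate reductase inhibitor,0.4,1.00,1
R01AA08,Naphazoline,Vasoconstrictor decongestant,0.4,0.90,1
R01AA05,Oxymetazoline,Vasoconstrictor decongestant,0.4,0.35,7
R01AA07,Xylometazoline,Vasoconstrictor decongestant,0.8,0.90,11
J05AH02,Oseltamivir carboxylate,Neuraminidase inhibitor antiviral,0.2,0.80,2
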