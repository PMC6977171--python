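# Solvent systems and molar compositions.
# Schema: label, role, component, molar_mass [g/mol], molar_ratio [-]
# role: des (deep eutectic solvent), conventional, water, extra
#   (extra = single DES constituents measured separately, e.g. lactic acid).
# Molar masses are standard average atomic-weight values (IUPAC 2021);
# PEG 300 uses its nominal mean molar mass of 300 g/mol.
# Glucose enters as the anhydrous species with water listed explicitly at
# the stated stoichiometry (the monohydrate's water is part of the ratio).
label,role,component,molar_mass,molar_ratio
CU,des,choline chloride,139.62,1
CU,des,urea,60.06,2
CG,des,choline chloride,139.62,1
CG,des,glycerol,92.09,2
CLW,des,choline chloride,139.62,1
CLW,des,lactic acid,90.08,0.9
CLW,des,water,18.015,0.6
BGW,des,betaine,117.15,1
BGW,des,glycerol,92.09,2
BGW,des,water,18.015,1
CGluW,des,choline chloride,139.62,1
CGluW,des,glucose,180.16,0.4
CGluW,des,water,18.015,1
LGluW,des,lactic acid,90.08,1
LGluW,des,glucose,180.16,0.2
LGluW,des,water,18.015,1.2
Ethanol,conventional,ethanol,46.07,1
Glycerol,conventional,glycerol,92.09,1
PEG300,conventional,PEG 300,300.0,1
Water,water,water,18.015,1
LacticAcid,extra,lactic acid,90.08,1
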