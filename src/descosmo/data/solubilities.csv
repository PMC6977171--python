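# Experimental saturation solubility of 11 APIs in 10 solvents after 24 h
# agitation at room temperature (triplicate shake-flask measurements),
# plus three measurements in lactic acid alone.
# Schema: api, api_molar_mass [g/mol], solvent, mean [mg API / g solvent],
#         sd [mg/g], n [-], flags (semicolon-separated; empty if none).
# Flags: below_LOQ (no mean reported), viscous (mixture turned too viscous
# to stir), phase_separation (solvent system demixed; no mean reported).
# API molar masses are standard average atomic-weight values.
api,api_molar_mass,solvent,mean,sd,n,flags
naproxen,230.26,CU,9.5,0.1,3,
naproxen,230.26,CG,4.4,0.1,3,
naproxen,230.26,CLW,14.2,0.1,3,
naproxen,230.26,BGW,4.6,0.2,3,
naproxen,230.26,LGluW,1.85,0.08,3,
naproxen,230.26,CGluW,2.89,0.06,3,
naproxen,230.26,Ethanol,110,6,3,
naproxen,230.26,Glycerol,1.25,0.05,3,
naproxen,230.26,PEG300,412,11,3,
naproxen,230.26,Water,0.0452,0.0005,3,
paracetamol,151.16,CU,123,4,3,
paracetamol,151.16,CG,94.8,0.8,3,
paracetamol,151.16,CLW,200.5,6,3,
paracetamol,151.16,BGW,80,6,3,
paracetamol,151.16,LGluW,26.2,2,3,
paracetamol,151.16,CGluW,54.0,2,3,
paracetamol,151.16,Ethanol,155,3,3,
paracetamol,151.16,Glycerol,20.9,0.3,3,
paracetamol,151.16,PEG300,102,1,3,
paracetamol,151.16,Water,7.9,0.2,3,
ibuprofen,206.28,CU,9,2,3,
ibuprofen,206.28,CG,4.5,0.8,3,
ibuprofen,206.28,CLW,14.0,0.5,3,
ibuprofen,206.28,BGW,4.9,0.2,3,
ibuprofen,206.28,LGluW,6.1,0.2,3,
ibuprofen,206.28,CGluW,1.30,0.1,3,
ibuprofen,206.28,Ethanol,467,18,3,
ibuprofen,206.28,Glycerol,2.3,0.1,3,
ibuprofen,206.28,PEG300,304,9,3,
ibuprofen,206.28,Water,0.055,0.004,3,
flufenamic acid,281.23,CU,2.19,0.05,3,
flufenamic acid,281.23,CG,1.05,0.05,3,
flufenamic acid,281.23,CLW,5.02,0.06,3,
flufenamic acid,281.23,BGW,11.8,1.0,3,
flufenamic acid,281.23,LGluW,0.085,0.003,3,
flufenamic acid,281.23,CGluW,0.176,0.006,3,
flufenamic acid,281.23,Ethanol,266,6,3,
flufenamic acid,281.23,Glycerol,0.45,0.06,3,
flufenamic acid,281.23,PEG300,303,15,3,
flufenamic acid,281.23,Water,0.0029,0.0001,3,
indomethacin,357.79,CU,8.4,0.1,3,
indomethacin,357.79,CG,5.0,0.2,3,
indomethacin,357.79,CLW,15.9,0.9,3,
indomethacin,357.79,BGW,23.0,0.6,3,
indomethacin,357.79,LGluW,5.06,0.05,3,
indomethacin,357.79,CGluW,0.95,0.00,3,
indomethacin,357.79,Ethanol,160,8,3,
indomethacin,357.79,Glycerol,1.34,0.08,3,
indomethacin,357.79,PEG300,632,23,3,
indomethacin,357.79,Water,0.055,0.004,3,
lidocaine,234.34,CU,1.36,0.06,3,
lidocaine,234.34,CG,5.77,0.07,3,
lidocaine,234.34,CLW,134.7,2,3,
lidocaine,234.34,BGW,3.48,0.02,3,
lidocaine,234.34,LGluW,459,15,3,
lidocaine,234.34,CGluW,1.2,0.1,3,viscous
lidocaine,234.34,Ethanol,20.5,0.7,3,
lidocaine,234.34,Glycerol,10.6,0.2,3,
lidocaine,234.34,PEG300,307,3,3,
lidocaine,234.34,Water,3.80,0.05,3,
theophylline,180.16,CU,2.2,0.2,3,
theophylline,180.16,CG,0.28,0.03,3,
theophylline,180.16,CLW,4.1,0.1,3,
theophylline,180.16,BGW,3.42,0.04,3,
theophylline,180.16,LGluW,63.5,0.5,3,
theophylline,180.16,CGluW,1.08,0.03,3,
theophylline,180.16,Ethanol,0.81,0.02,3,
theophylline,180.16,Glycerol,1.66,0.07,3,
theophylline,180.16,PEG300,1.23,0.09,3,
theophylline,180.16,Water,6.4,0.1,3,
celecoxib,381.37,CU,1.78,0.03,3,
celecoxib,381.37,CG,3.86,0.02,3,
celecoxib,381.37,CLW,18.6,0.0,3,
celecoxib,381.37,BGW,3.25,0.04,3,
celecoxib,381.37,LGluW,1.81,0.00,3,
celecoxib,381.37,CGluW,0.40,0.02,3,
celecoxib,381.37,Ethanol,100,5,3,
celecoxib,381.37,Glycerol,0.33,0.03,3,
celecoxib,381.37,PEG300,395,36,3,
celecoxib,381.37,Water,0.00148,0.00007,3,
aprepitant,534.43,CU,0.0133,0.0003,3,
aprepitant,534.43,CG,0.0038,0.009,3,
aprepitant,534.43,CLW,2.03,0.3,3,
aprepitant,534.43,BGW,0.058,0.009,3,
aprepitant,534.43,LGluW,7.2,0.1,3,
aprepitant,534.43,CGluW,0.031,0.02,3,
aprepitant,534.43,Ethanol,4.9,0.3,3,
aprepitant,534.43,Glycerol,0.973,0.06,3,
aprepitant,534.43,PEG300,1.0,0.2,3,
aprepitant,534.43,Water,,,3,below_LOQ
probucol,516.84,CU,0.0318,0.001,3,
probucol,516.84,CG,0.02,0.01,3,
probucol,516.84,CLW,0.03,0.01,3,
probucol,516.84,BGW,0.067,0.009,3,
probucol,516.84,LGluW,0.010,0.004,3,
probucol,516.84,CGluW,0.034,0.03,3,
probucol,516.84,Ethanol,36,2,3,
probucol,516.84,Glycerol,0.3,0.2,3,
probucol,516.84,PEG300,19.0,0.2,3,
probucol,516.84,Water,,,3,below_LOQ
cinnarizine,368.51,CU,0.013,0.004,3,
cinnarizine,368.51,CG,0.06,0.02,3,
cinnarizine,368.51,CLW,2.8,0.5,3,
cinnarizine,368.51,BGW,0.04,0.03,3,
cinnarizine,368.51,LGluW,,,3,phase_separation
cinnarizine,368.51,CGluW,0.038,0.03,3,
cinnarizine,368.51,Ethanol,9.5,0.5,3,
cinnarizine,368.51,Glycerol,0.03,0.01,3,
cinnarizine,368.51,PEG300,12.4,0.3,3,
cinnarizine,368.51,Water,0.0006,0.0001,3,
paracetamol,151.16,LacticAcid,96.5,5.5,3,
theophylline,180.16,LacticAcid,116.4,2.7,3,
aprepitant,534.43,LacticAcid,83.5,22.8,3,
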