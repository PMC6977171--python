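# descosmo interaction parameters — shipped defaults, version 1.
# Misfit and HB coefficients are the open COSMO-SAC reparameterization
# constants (Lin & Sandler 2002: alpha' = 16466.72 kcal A^4 mol^-1 e^-2,
# c_hb = 85580 kcal A^4 mol^-1 e^-2, a_eff = 7.5 A^2) converted to this
# package's per-area kJ units: c_misfit = alpha'/(2 a_eff), c_hb/a_eff.
# sigma_hb is the +-0.0082 e/A^2 donor/acceptor threshold.
temperature 298.15  # [K]
a_eff 7.5  # [A^2]
c_misfit 4593.1170986666675  # [kJ/mol/A^2/(e/A^2)^2]
c_hb 47742.22933333334  # [kJ/mol/A^2/(e/A^2)^2]
sigma_hb 0.0082  # [e/A^2]
hb_form donor_acceptor  # [-]
combinatorial_form none  # [-]
combinatorial_z 10.0  # [-]
version 1  # [-]
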