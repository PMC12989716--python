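# Baseline ODE model parameters (the values used in all default simulations).
alpha: 0.3          # normal cell intrinsic growth rate (/day)
beta: 0.45          # cancer cell intrinsic growth rate (/day)
K: 10000            # carrying capacity (cells)
delta: 0.1          # intrinsic death rate (/day)
eta: 1.0            # probability of successful endocycle
psi: 50             # chronic-stress onset time (days)
mu_max: 0.01        # mutation-rate ceiling (/division)
mu_slope: 0.4       # mutation sigmoid slope (per % endocycle frequency)
mu_mid: 5           # mutation sigmoid midpoint (% endocycle frequency)
phiN_max: 0.02      # endocycle entry rate ceiling (/day)
phiN_slope: 0.06    # endocycle entry sigmoid slope (/day)
phiN_mid: 125       # endocycle entry sigmoid midpoint (days)
phiE_base: 0.01     # ploidy reduction floor (/day)
phiE_amp: 0.04      # ploidy reduction amplitude (/day)
phiE_slope: 0.06    # ploidy reduction sigmoid slope (/day)
phiE_mid: 125       # ploidy reduction sigmoid midpoint (days)
kappa_base: 0.01    # immune killing floor (/day)
kappa_amp: 0.15     # immune killing amplitude (/day)
kappa_slope: 0.4    # immune killing sigmoid slope (per %)
kappa_mid: 5        # immune killing sigmoid midpoint (%)
literal_phie: false # per-capita ploidy-reduction flux (see model docs)
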