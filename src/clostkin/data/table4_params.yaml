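# Fitted kinetic parameter set for the high-producing mutant strain.
# beta_Aa is unreported in the source table ("-") and defaults to 0.
mu_m: 0.48      # maximum specific growth rate, 1/h
K_S: 1.71       # substrate saturation constant, g/L
K_I: 383.0      # substrate inhibition constant, g/L
P_d: 53.8       # critical total-acid concentration, g/L
i: 5.32         # product-inhibition exponent
K_d: 0.0027     # specific death rate, 1/h
alpha_Ba: 3.12  # growth-associated butyrate coefficient, g/g DCW
alpha_Aa: 0.83  # growth-associated acetate coefficient, g/g DCW
beta_Ba: 0.049  # non-growth butyrate coefficient, g/g DCW/h
beta_Aa: 0.0    # non-growth acetate coefficient, g/g DCW/h
Y_X: 0.812      # biomass yield factor, g/g
Y_Ba: 0.973     # butyrate yield factor, g/g
Y_Aa: 0.997     # acetate yield factor, g/g
m_S: 0.015      # maintenance coefficient, 1/h
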