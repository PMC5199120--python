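# Reference parameter set for the simplified carousel model
# (yeast pheromone response; concentrations nM, time s).
kinetics:
  Kd_LR: 5.6          # nM, ligand-receptor dissociation constant
  koff_LR: 0.001      # 1/s, ligand-receptor off-rate
  Kd_RG: 33.0         # nM, receptor-Galpha dissociation constant
  koff_RG: 0.1        # 1/s, receptor-Galpha off-rate
  Kd_GdGbg: 0.01      # nM, GalphaGDP-Gbg dissociation constant
  kA_Gd: 3.2          # 1/(nM s), GalphaGDP + Gbg association rate
  kE_G: 0.00062       # 1/s, exchange, uncoupled trimer
  kE_RG: 0.00062      # 1/s, exchange, coupled to unoccupied receptor
  kE_LRG: 1.5         # 1/s, exchange, coupled to occupied receptor
  kH_Gt: 0.002        # 1/s, hydrolysis, uncoupled GalphaGTP
  kH_RGt: 0.11        # 1/s, hydrolysis, coupled to unoccupied receptor
  kH_LRGt: 0.11       # 1/s, hydrolysis, coupled to occupied receptor
abundances:
  R_tot: 1400.0       # nM, total receptor
  G_tot: 860.0        # nM, total G protein (Galpha = Gbg)
  V_cyt_fl: 36.4      # fl, cytosolic volume for molecule-count conversion
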