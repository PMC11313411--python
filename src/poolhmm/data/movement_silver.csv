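# Published posterior-mean monthly movement probabilities for silver carp in the
# six-pool Illinois Waterway study reach (product of survival, battery retention
# and pool-transition probability). Rows = destination pool, columns = origin pool,
# ordered downstream to upstream: Alton, La Grange, Peoria, Starved Rock,
# Marseilles, Dresden Island. Fixture for validating matrix reductions only;
# never used as model input.
pool,Alton,LaGrange,Peoria,StarvedRock,Marseilles,DresdenIsland
Alton,0.747,0.007,0.000,0.000,0.139,0.132
LaGrange,0.007,0.824,0.270,0.040,0.059,0.000
Peoria,0.000,0.050,0.626,0.039,0.002,0.000
StarvedRock,0.001,0.029,0.039,0.856,0.010,0.000
Marseilles,0.100,0.025,0.000,0.000,0.724,0.011
DresdenIsland,0.080,0.000,0.000,0.000,0.001,0.792
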