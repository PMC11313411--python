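# Published posterior-mean monthly movement probabilities for bighead carp in the
# six-pool Illinois Waterway study reach (product of survival, battery retention
# and pool-transition probability). Rows = destination pool, columns = origin pool,
# ordered downstream to upstream: Alton, La Grange, Peoria, Starved Rock,
# Marseilles, Dresden Island. Fixture for validating matrix reductions only;
# never used as model input.
pool,Alton,LaGrange,Peoria,StarvedRock,Marseilles,DresdenIsland
Alton,0.783,0.074,0.001,0.001,0.060,0.102
LaGrange,0.015,0.768,0.021,0.015,0.120,0.000
Peoria,0.001,0.008,0.806,0.206,0.000,0.057
StarvedRock,0.001,0.001,0.073,0.695,0.020,0.003
Marseilles,0.040,0.087,0.001,0.021,0.721,0.017
DresdenIsland,0.097,0.000,0.036,0.000,0.016,0.758
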