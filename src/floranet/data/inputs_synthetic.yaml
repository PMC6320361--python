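# SYNTHETIC reconstruction of the constant external input levels (nM) for the
# four independent input genes: SVP and FLC expression in the meristem (x7, x8)
# and in the leaves (x9, x10).
#
# The original experimental levels are not available here.  These values are
# back-solved from the published positive equilibrium of the six-gene model:
# only the products kappa11(x7)*kappa12(x8) and kappa15(x9)*kappa16(x10) enter
# the steady-state relations, so within each product the two levels are set
# equal.  With these levels the model reproduces the published equilibrium
# (AP1 121.567, LFY 452.395, SOC1 827.835, FD 1113.882, AGL24 86881.258,
# FT 2.037 nM) to ~2e-5 relative, and the constant FT level is u = 2.037 nM
# exactly.
units: nM
values:
  x7: 1.5293422547642660   # SVP, meristem
  x8: 1.5293422547642660   # FLC, meristem
  x9: 137.74986867446340   # SVP, leaves
  x10: 137.74986867446340  # FLC, leaves
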