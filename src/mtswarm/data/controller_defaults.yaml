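# Calibrated defaults of the DNA controller (nM, minutes).
# These rate constants are a documented calibration, not a measurement:
# with all enzyme activities at 1 the free-linker pulse peaks near 15 min
# and decays below 5% of its peak by ~60 min; with the restriction enzyme
# disabled the pulse plateaus instead of decaying.
species:
  template: 10.0
  converter: 100.0
  transducer: 100.0
  receptor1: 25.0
  receptor2: 25.0
rates:
  k_amp: 0.8      # /min        lumped signal amplification (polymerase+nickase cycle)
  k_conv: 0.012   # /(nM.min)   signal + Converter -> linker
  k_trans: 0.0012 # /(nM.min)   signal + Transducer -> updater (shorter toehold)
  k_upd: 0.012    # /(nM.min)   updater + Template -> Template.updater
  k_cut: 0.1      # /min        restriction cut of Template.updater
  k_damp: 1.2     # /min        lumped dissociator amplification
  k_bridge: 0.004 # /(nM.min)   linker + receptor association
  k_rem: 0.02     # /(nM.min)   dissociator-mediated linker inactivation
enzymes:
  polymerase: 1.0
  nickase: 1.0
  restriction: 1.0
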