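# Combination therapy in a less permeable tumor: 100 nm vessel-wall pores
# (same 100 nm carriers), otherwise identical to combo_9h.
mode: combination
field:
  amplitude: 13.0e3
  frequency: 400.0e3
  safety_product_limit: 5.3e9
schedule:
  delay: 9
  amf_duration: 1
  horizon: 72
drug:
  vessel_pore_diameter: 100   # nm
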