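# Combination therapy: TSL-Dox bolus at t = 0, AMF (13 kA/m, 400 kHz,
# 60 min) applied 9 h later, followed to 72 h post-injection.
mode: combination
field:
  amplitude: 13.0e3
  frequency: 400.0e3
  safety_product_limit: 5.3e9
schedule:
  delay: 9      # h
  amf_duration: 1
  horizon: 72
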