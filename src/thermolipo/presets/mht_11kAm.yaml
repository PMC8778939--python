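# Magnetic hyperthermia alone, 400 kHz / 11 kA/m, 60 min exposure.
mode: mht_only
field:
  amplitude: 11.0e3   # A/m
  frequency: 400.0e3  # Hz
schedule:
  delay: 0
  amf_duration: 1     # h
  horizon: 4          # h (heating + cool-down window)
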