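# Magnetic hyperthermia alone, 400 kHz / 13 kA/m, 60 min exposure.
# H*f = 5.2e9 A/(m s) sits above the usual 5e9 clinical comfort bound;
# the limit is raised explicitly to mirror the studied exposure.
mode: mht_only
field:
  amplitude: 13.0e3
  frequency: 400.0e3
  safety_product_limit: 5.3e9
schedule:
  delay: 0
  amf_duration: 1
  horizon: 4
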