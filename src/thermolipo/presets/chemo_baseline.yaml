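# Conventional chemotherapy: free doxorubicin bolus, no heating.
mode: chemo
schedule:
  delay: 0          # h
  amf_duration: 1   # h (unused in chemo mode)
  horizon: 72       # h
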