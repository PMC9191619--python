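analyte,PROBE-001,PROBE-002
example-analyte,100.0,37.5
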