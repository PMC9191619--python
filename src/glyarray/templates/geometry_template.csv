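Block,Row,Column,ID,Name,Concentration,Dose
1,1,1,PROBE-001,Example probe,50 µM,
1,1,2,PROBE-001,Example probe,50 µM,
1,1,3,EMPTY,,,
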