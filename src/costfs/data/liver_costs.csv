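feature,cost
Mcv,16
Alkphos,20
Sgpt,45
Sgot,28
Gammagt,33
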