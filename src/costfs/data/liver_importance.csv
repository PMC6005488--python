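feature,ls
Mcv,0.8456
Alkphos,0.7439
Sgpt,0.9506
Sgot,0.9345
Gammagt,0.9680
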