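Patient,Mcv,Alkphos,Sgpt,Sgot,Gammagt,Selector
x1,0.53,0.60,0.27,0.29,0.09,1
x2,0.68,0.36,0.20,0.35,0.12,2
x3,0.55,0.27,0.19,0.14,0.17,2
x4,0.68,0.48,0.20,0.25,0.11,1
x5,0.58,0.57,0.05,0.30,0.08,2
x6,0.87,0.28,0.06,0.20,0.09,1
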