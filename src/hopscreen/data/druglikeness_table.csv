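name,rule_of_5,rule_of_3
TC03.1,1,1
TC03.10,2,1
TC03.14,1,1
TC03.15,1,1
SSI-2‡,1,1
TC03.18,2,1
TC03.23,1,1
TC03.31,1,1
TC03.32,1,1
TC03.33,2,1
TC03.37,1,1
TC03.4,1,1
TC03.41,1,1
SSI-3‡,1,1
TC03.46,1,1
TC03.47,1,1
TC03.48,2,1
TC03.5,1,1
TC03.53,2,1
TC03.56,1,1
TC03.6,1,1
TC03.60,1,1
TC03.61,1,1
TC03.66,2,1
TC03.8,2,1
SetA.100 control,0,1
SSI-4‡,0,0
SetA.59,0,0
SetA.61,0,0
SetA.68,0,0
SetA.69,0,0
SetA.70,0,0
SSI-1‡,0,1
SetB.34,0,1
SetB.49,0,0
SetB.52,0,1
SetB.6,0,1
SetB.61,0,1
SetB.66,0,1
SetB.69,0,1
SetB.7,0,1
SetB.73,0,1
SetB.74,0,0
SetB.75,0,0
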