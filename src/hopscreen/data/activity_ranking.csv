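name,rank,single_pt_active_10uM,known_ic50_nM,predicted_ic50_nM,under_500nM,mw
DaiichiSankyo 3nM,1,NA,3,1.87,Y,452.45
CVT-12-012 36nM,2,NA,36,13.52,Y,434.42
SAR707 8nM,3,NA,8,14.49,Y,466.46
TC03.10,4,No,,30.98,Y,537.58
TC03.48,5,No,,40.83,Y,538.57
Abbott 10b,6,NA,58,52.61,Y,464.32
Abbott 7c,7,NA,51,67.77,Y,419.87
TC03.1,8,Not tested,,70.96,Y,469.46
TC03.100 Blind Control 10-40 nM SAR707,9,NA,,72.62,Y,418.90
TC03.18,10,No,,72.62,Y,519.54
Abbott 10g,11,NA,100,91.42,Y,436.44
SetA.70,12,No,,91.42,Y,408.90
TC03.4,13,Y,,104.71,N,456.46
TC03.14,14,No,,109.91,Y,483.49
SSI-3,15,Y,,126.19,Y,498.50
TC03.6,16,No,,129.13,Y,495.50
TC03.37,17,Y,,155.25,Y,539.56
Analog3,18,NA,107,170.23,Y,443.43
SetB.74,19,No,,170.23,Y,420.43
DaiichiSankyo,20,NA,100,178.25,Y,514.63
Xenon LCF369,21,NA,120,182.40,Y,465.45
TC03.61,22,Y,,191.00,Y,510.56
TC03.8,23,No,,219.30,Y,523.55
SetA.69,24,Y,,224.40,Y,394.87
MerckFrost MF-152,25,NA,100,240.45,Y,384.38
TC03.15,26,Y,,246.05,Y,483.49
SetB.68,27,No,,282.51,Y,392.38
SetB.73,28,No,,289.09,Y,406.40
SetA.61,29,No,,302.71,Y,395.86
TC03.46,30,No,,302.71,Y,483.49
SetB.70,31,No,,331.92,Y,407.39
SSI-4,32,Y,7,339.65,Y,388.85
A939572 37nM,33,NA,37,372.42,Y,387.87
SSI-2,34,Y,,381.09,Y,484.48
Abbott 10e,35,NA,470,447.74,Y,405.40
TC03.5,36,Y,,468.85,Y,470.49
TC03.66,37,Y,,468.85,Y,523.55
TC03.23,38,Y,,479.77,Y,526.51
SetB.52,39,No,,479.77,Y,473.49
SetB.61,40,No,,550.85,N,484.48
TC03.31,41,No,,632.46,N,497.52
SetB.66,42,No,,709.63,N,406.40
TC03.53,43,No,,726.16,N,524.54
Abbott,44,NA,400,833.74,N,353.42
TC03.47,45,No,,853.16,N,533.56
"SetA.100 Blind Control 400 nM (28c, Abbott ChemBL375265)",46,NA,400,873.03,N,389.84
SetB.49,47,No,,957.26,N,469.48
Abbott 10a,48,NA,6000,1099.08,N,385.42
SSI-1,49,Y,,1099.08,N,449.43
TC03.56,50,N,,1177.69,N,483.49
SetA.68,51,Y (no rescue),,1321.39,N,397.88
TC03.41,52,Y,,1352.17,N,497.52
SetA.1,53,No,,1482.62,N,385.85
SetB.69,54,No,,1482.62,N,420.43
SetB.34,55,No,,2760.77,N,392.38
Abbott 10h,56,NA,10000,5508.46,N,397.43
SetB.75,57,No,,5902.42,N,463.46
Analog2,58,NA,2680,49094.18,N,381.35
Analog1,59,NA,10000000,166352.75,N,367.33
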