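rank,name,dock_norm,shape_norm,qsar_norm,z_sum,z_avg
1,SSI-2‡,0.99,0.77,0.90,2.67,0.89
2,TC03.18,0.91,0.77,0.96,2.64,0.88
3,SSI-3‡,0.88,0.81,0.94,2.62,0.87
4,SAR707 8nM (TC03.100),0.63,1.00,0.96,2.59,0.86
5,TC03.14,0.84,0.79,0.95,2.58,0.86
6,TC03.46,0.92,0.81,0.85,2.58,0.86
7,TC03.10,0.84,0.74,0.98,2.56,0.85
8,TC03.37,0.85,0.71,0.92,2.48,0.83
9,TC03.1,0.78,0.71,0.96,2.45,0.82
10,TC03.6,0.73,0.76,0.94,2.42,0.81
11,TC03.23,0.90,0.72,0.76,2.37,0.79
12,TC03.48,0.57,0.80,0.98,2.34,0.78
13,TC03.61,0.72,0.80,0.81,2.33,0.78
14,TC03.31,0.91,0.71,0.68,2.31,0.77
15,TC03.5,0.84,0.70,0.77,2.30,0.77
16,SetB.74,0.78,0.57,0.91,2.27,0.76
17,Abbott 10g phenoxyl 100nM,0.77,0.54,0.95,2.26,0.75
18,TC03.15,0.63,0.74,0.88,2.25,0.75
19,Abbott 7c 2chlorophenoxyl 51nM,0.85,0.43,0.97,2.24,0.75
20,SSI-4‡,0.78,0.62,0.83,2.23,0.74
21,SetB.73,0.78,0.60,0.86,2.23,0.74
22,DaiichiSankyo 3nM,0.67,0.64,0.91,2.23,0.74
23,SetB.7,0.77,0.58,0.88,2.23,0.74
24,TC03.53,0.84,0.71,0.64,2.19,0.73
25,Merck Inhibitor <100 nM,0.70,0.47,1.00,2.16,0.72
26,TC03.47,0.89,0.68,0.57,2.15,0.72
27,SetB.61,0.69,0.62,0.82,2.13,0.71
28,TC03.7,0.80,0.73,0.55,2.08,0.69
29,TC03.8,0.44,0.73,0.89,2.07,0.69
30,SetA.69,0.74,0.42,0.89,2.05,0.68
31,SetB.6,0.68,0.58,0.74,2.00,0.67
32,SetB.52,0.57,0.64,0.76,1.96,0.65
33,SetB.66,0.71,0.60,0.65,1.95,0.65
34,TC03.66,0.52,0.65,0.77,1.93,0.64
35,TC03.56,0.86,0.65,0.41,1.92,0.64
36,SetA.61,0.67,0.40,0.85,1.92,0.64
37,SetA.70,0.55,0.39,0.95,1.89,0.63
38,SetB.69,0.82,0.62,0.26,1.70,0.57
39,SetA.100 control (400nM),0.72,0.40,0.56,1.68,0.56
40,SetB.49,0.57,0.57,0.52,1.67,0.56
41,SSI-1‡,0.60,0.61,0.45,1.66,0.55
42,TC03.41,0.57,0.72,0.32,1.62,0.54
43,SetA.68,0.74,0.38,0.34,1.46,0.49
44,SetA.59,0.72,0.40,0.31,1.42,0.47
45,DaiichiSankyo IC50 100 nM,0.87,0.52,0.00,1.39,0.46
46,Abbott 10d phenoxyl 51nM,0.85,0.45,0.00,1.30,0.43
47,Abbott 10c phenoxyl 38nM,0.81,0.42,0.00,1.23,0.41
48,SetA.1,0.54,0.39,0.26,1.19,0.40
49,SetB.34,0.80,0.56,-0.38,0.98,0.33
50,SetB.75,0.57,0.58,-1.05,0.09,0.03
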