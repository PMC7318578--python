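enzyme,temperature_K,metabolite,Vmax,Vmax_SE,KM,KM_SE
BM3 M11,277.0,3'-OH-MF,135,10,72,16
BM3 M11,277.0,4'-OH-MF,230,19,76,17
BM3 M11,277.0,5-OH-MF,24,3,77,22
BM3 M11,283.4,3'-OH-MF,212,9,140,18
BM3 M11,283.4,4'-OH-MF,343,12,151,15
BM3 M11,283.4,5-OH-MF,34,2,124,19
BM3 M11,290.2,3'-OH-MF,561,44,161,14
BM3 M11,290.2,4'-OH-MF,859,82,170,17
BM3 M11,290.2,5-OH-MF,85,8,148,15
BM3 M11,292.7,3'-OH-MF,498,33,145,45
BM3 M11,292.7,4'-OH-MF,736,52,159,52
BM3 M11,292.7,5-OH-MF,72,4,188,37
BM3 M11,298.6,3'-OH-MF,463,33,85,20
BM3 M11,298.6,4'-OH-MF,608,50,88,23
BM3 M11,298.6,5-OH-MF,64,7,86,25
BM3 M11,304.4,3'-OH-MF,607,53,266,56
BM3 M11,304.4,4'-OH-MF,787,41,354,34
BM3 M11,304.4,5-OH-MF,81,7,409,165
BM3 M11,313.3,3'-OH-MF,358,28,556,200
BM3 M11,313.3,4'-OH-MF,431,37,603,150
BM3 M11,313.3,5-OH-MF,42,5,384,202
BM3 M11,317.6,3'-OH-MF,194,19,388,184
BM3 M11,317.6,4'-OH-MF,208,14,538,34
BM3 M11,317.6,5-OH-MF,21,2,762,118
CYP1A2,279.4,4'-OH-MF,0.56,0.13,204,118
CYP1A2,279.4,5-OH-MF,0.50,0.02,6,2
CYP1A2,287.7,4'-OH-MF,0.99,0.17,210,92
CYP1A2,287.7,5-OH-MF,0.78,0.09,47,21
CYP1A2,299.4,4'-OH-MF,0.91,0.18,144,68
CYP1A2,299.4,5-OH-MF,0.67,0.03,42,7
CYP1A2,309.8,4'-OH-MF,1.0,0.09,182,33
CYP1A2,309.8,5-OH-MF,0.68,0.02,47,4
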