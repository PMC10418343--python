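substituent,sigma
H,0.00
p-CH3,-0.17
p-OCH3,-0.27
p-C2H5,-0.15
p-F,0.06
p-Cl,0.23
p-Br,0.23
p-I,0.18
p-OH,-0.37
p-NH2,-0.66
p-NO2,0.78
p-CN,0.66
p-CF3,0.54
m-CH3,-0.07
m-OCH3,0.12
m-F,0.34
m-Cl,0.37
m-Br,0.39
m-NO2,0.71
m-CN,0.56
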