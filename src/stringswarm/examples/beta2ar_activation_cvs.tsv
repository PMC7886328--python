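# β2-adrenergic receptor activation CVs: inverse inter-residue Cα distance
# pairs (Ballesteros–Weinstein numbering in parentheses) with RBM/LRP
# importance weights.  Demonstrates the CV-table serialization format.
F223(5.62)-A271(6.33)	1.0
Q224(5.63)-K227(5.66)	0.97
F223(5.62)-L272(6.34)	0.76
I325(7.52)-R328(7.55)	0.73
F223(5.62)-K227(5.66)	0.72
A226(5.65)-K267(6.29)	0.69
V54(1.53)-C327(7.54)	0.67
L324(7.51)-R328(7.55)	0.67
A134(3.53)-Y141	0.66
I135(3.54)-L272(6.34)	0.6
V222(5.61)-A271(6.33)	0.59
A226(5.65)-E268(6.30)	0.59
Q26(1.25)-D29(1.28)	0.57
I135(3.54)-E225(5.64)	0.57
R131(3.50)-L275(6.37)	0.57
A134(3.53)-A271(6.33)	0.56
C285(6.47)-V317(7.43)	0.56
A76(2.47)-P323(7.50)	0.56
Q26(1.25)-E30(1.29)	0.55
A226(5.65)-A271(6.33)	0.54
I121(3.40)-F208(5.47)	0.53
E338(8.56)-R343	0.53
I334(8.52)-R344	0.52
G50(1.49)-L324(7.51)	0.49
T25-D29(1.28)	0.47
I135(3.54)-A271(6.33)	0.46
T25-E30(1.29)	0.46
W286(6.48)-G315(7.41)	0.45
C285(6.47)-N318(7.45)	0.44
Q27(1.26)-E30(1.29)	0.44
R63-D331(8.49)	0.43
Q197(5.37)-V297(6.59)	0.43
A134(3.53)-E268(6.30)	0.42
P288(6.50)-L311(7.37)	0.42
T281(6.43)-N318(7.45)	0.42
C341(8.59)-R344	0.42
I135(3.54)-P138	0.4
R328(7.55)-R333(8.51)	0.36
L311(7.37)-G315(7.41)	0.36
I135(3.54)-E268(6.30)	0.35
C285(6.47)-I314(7.40)	0.34
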