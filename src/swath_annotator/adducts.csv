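name,polarity,mass_delta,mode
[M]+,positive,-0.0005485799,default
[M+H]+,positive,1.0072764522,default
[M+Na]+,positive,22.9892207010,default
[M+NH4]+,positive,18.0338255532,default
[M+K]+,positive,38.9631581001,default
[M-H]-,negative,-1.0072764522,default
[M+Na-2H]-,negative,20.9746677967,default
[M+NH4-2H]-,negative,16.0192726489,default
[M-Cl]-,negative,34.9694012599,default
[M-Cl]-,negative,-34.9683041001,strict
[M+K-2H]-,negative,36.9486051959,default
[M+FA-H]-,negative,44.9982028512,default
[M+H2O-H]-,negative,17.0032882316,default
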