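element,monoisotopic_mass_da
H,1.00782503207
C,12.0
N,14.0030740048
O,15.9949146196
F,18.99840322
Na,22.9897692809
Si,27.9769265325
P,30.97376163
S,31.97207100
Cl,34.96885268
K,38.96370668
Br,78.9183371
I,126.904473
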