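# group	pk
n_term	7.50
c_term	3.55
C	9.00
D	4.05
E	4.45
H	5.98
K	10.00
R	12.00
Y	10.00
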