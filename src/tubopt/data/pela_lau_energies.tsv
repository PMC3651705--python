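drug	betaI	betaIIa	betaIIb	betaIII	betaIVa	betaIVb	betaV	betaVI	unit
PELA	-22.6	-20.3	-10.6	-7.9	-18.2	-2.1	-22.0	0	unspecified
LAU	0	0	-30.0	0	0	-21.9	-34.9	0	unspecified
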