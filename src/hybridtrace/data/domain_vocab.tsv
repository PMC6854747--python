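# signature accession -> domain token mapping (editable)
# Pfam signatures commonly reported for fungal PKS/NRPS catalytic domains
PF00109	KS
PF02801	KS
PF16197	KS
PF00698	AT
PF00501	A
PF00668	C
PF00550	T
PF00975	TE
PF08659	KR
PF14765	DH
PF08241	MT
PF08242	MT
PF00107	ER
PF07993	R
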