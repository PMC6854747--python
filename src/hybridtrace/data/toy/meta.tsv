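tip_id	species	section	sm_class	compound
nig1_h1	nig1	Nigri	PKS-NRPS	
nig1_h2	nig1	Nigri	PKS-NRPS	
nig2_h1	nig2	Nigri	PKS-NRPS	
nig2_h2	nig2	Nigri	NRPS-PKS	
nig3_h1	nig3	Nigri	PKS-NRPS	
nig3_h2	nig3	Nigri	PKS-NRPS	
fla1_h1	fla1	Flavi	PKS-NRPS	
fla1_h2	fla1	Flavi	NRPS-PKS	
fla2_h1	fla2	Flavi	PKS-NRPS	
fla2_h2	fla2	Flavi	PKS-NRPS	
fla3_h1	fla3	Flavi	PKS-NRPS	
fla3_h2	fla3	Flavi	PKS-NRPS	
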