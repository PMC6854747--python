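((((nig1_h1:0.05,nig1_h2:0.05):0.05,(nig2_h1:0.05,nig2_h2:0.05):0.05):0.05,((nig3_h1:0.05,nig3_h2:0.05):0.1,fla3_h2:0.2):0.05):1.0,(((fla1_h1:0.05,fla1_h2:0.05):0.05,(fla2_h1:0.05,fla2_h2:0.05):0.05):0.05,fla3_h1:0.15):1.0);
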