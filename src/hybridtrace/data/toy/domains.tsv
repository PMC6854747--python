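nig1_h1	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
nig1_h1	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
nig1_h1	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
nig1_h1	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
nig1_h1	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
nig1_h1	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
nig1_h1	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
nig1_h2	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
nig1_h2	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
nig1_h2	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
nig1_h2	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
nig1_h2	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
nig1_h2	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
nig1_h2	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
nig2_h1	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
nig2_h1	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
nig2_h1	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
nig2_h1	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
nig2_h1	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
nig2_h1	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
nig2_h1	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
nig2_h2	md5	2000	Pfam	PF00668	desc	1	430	1e-30	T	2020-01-01
nig2_h2	md5	2000	Pfam	PF00501	desc	460	940	1e-30	T	2020-01-01
nig2_h2	md5	2000	Pfam	PF00550	desc	960	1030	1e-30	T	2020-01-01
nig2_h2	md5	2000	Pfam	PF00109	desc	1060	1480	1e-30	T	2020-01-01
nig2_h2	md5	2000	Pfam	PF00698	desc	1510	1800	1e-30	T	2020-01-01
nig3_h1	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
nig3_h1	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
nig3_h1	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
nig3_h1	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
nig3_h1	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
nig3_h1	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
nig3_h1	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
nig3_h2	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
nig3_h2	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
nig3_h2	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
nig3_h2	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
nig3_h2	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
nig3_h2	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
nig3_h2	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
fla1_h1	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
fla1_h1	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
fla1_h1	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
fla1_h1	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
fla1_h1	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
fla1_h1	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
fla1_h1	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
fla1_h2	md5	2000	Pfam	PF00668	desc	1	430	1e-30	T	2020-01-01
fla1_h2	md5	2000	Pfam	PF00501	desc	460	940	1e-30	T	2020-01-01
fla1_h2	md5	2000	Pfam	PF00550	desc	960	1030	1e-30	T	2020-01-01
fla1_h2	md5	2000	Pfam	PF00109	desc	1060	1480	1e-30	T	2020-01-01
fla1_h2	md5	2000	Pfam	PF00698	desc	1510	1800	1e-30	T	2020-01-01
fla2_h1	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
fla2_h1	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
fla2_h1	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
fla2_h1	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
fla2_h1	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
fla2_h1	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
fla2_h1	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
fla2_h2	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
fla2_h2	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
fla2_h2	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
fla2_h2	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
fla2_h2	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
fla2_h2	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
fla2_h2	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
fla3_h1	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
fla3_h1	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
fla3_h1	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
fla3_h1	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
fla3_h1	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
fla3_h1	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
fla3_h1	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
fla3_h2	md5	2000	Pfam	PF00109	desc	1	200	1e-30	T	2020-01-01
fla3_h2	md5	2000	Pfam	PF00109	desc	260	420	1e-30	T	2020-01-01
fla3_h2	md5	2000	Pfam	PF00698	desc	450	740	1e-30	T	2020-01-01
fla3_h2	md5	2000	Pfam	PF00550	desc	760	830	1e-30	T	2020-01-01
fla3_h2	md5	2000	Pfam	PF00668	desc	860	1290	1e-30	T	2020-01-01
fla3_h2	md5	2000	Pfam	PF00501	desc	1320	1800	1e-30	T	2020-01-01
fla3_h2	md5	2000	Pfam	PF00550	desc	1850	1920	1e-30	T	2020-01-01
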