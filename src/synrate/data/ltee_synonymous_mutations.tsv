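# Synonymous base substitutions observed in 19 sequenced clones from 8
# non-mutator populations of the 40,000-generation E. coli long-term
# evolution experiment. One row per (event, carrying clone): 35 independent
# events expanded to 52 clone-level records. Positions are 1-based
# coordinates on the ancestral REL606 chromosome.
population	clone	generation	position	gene	ref	alt	coding_class
Ara-3	30K-B	30000	756799	tolR	C	T	synonymous
Ara-3	40K	40000	756799	tolR	C	T	synonymous
Ara-3	30K-B	30000	2613609	purL	G	A	synonymous
Ara-3	30K-B	30000	2642843	yfiQ	G	T	synonymous
Ara-3	40K	40000	2983794	yggW	C	T	synonymous
Ara-3	40K	40000	3141566	ygjE	C	T	synonymous
Ara-3	40K	40000	3407922	kefB	C	A	synonymous
Ara-3	30K-A	30000	4111342	metL	C	T	synonymous
Ara-3	30K-A	30000	4177963	hemE	T	G	synonymous
Ara-3	30K-B	30000	4107018	ECB_03822	T	A	synonymous
Ara-3	40K	40000	4107018	ECB_03822	T	A	synonymous
Ara-3	40K	40000	4313510	eptA	C	T	synonymous
Ara-5	40K-B	40000	157626	htrE	A	T	synonymous
Ara-5	40K-A	40000	307594	yahC	C	T	synonymous
Ara-5	40K-B	40000	307594	yahC	C	T	synonymous
Ara-5	40K-C	40000	307594	yahC	C	T	synonymous
Ara-5	40K-A	40000	3107610	ygiN	T	A	synonymous
Ara-5	40K-B	40000	3107610	ygiN	T	A	synonymous
Ara-5	40K-C	40000	3107610	ygiN	T	A	synonymous
Ara-6	40K-B	40000	857058	moeB	C	T	synonymous
Ara-6	40K-B	40000	1352030	sapC	G	T	synonymous
Ara-6	40K-A	40000	2087738	mdtA	C	A	synonymous
Ara-6	40K-B	40000	2087738	mdtA	C	A	synonymous
Ara-6	40K-A	40000	2095621	mdtD	G	A	synonymous
Ara-6	40K-B	40000	3482212	malT	G	A	synonymous
Ara+1	40K-A	40000	132062	lpd	C	T	synonymous
Ara+1	40K-B	40000	239002	dnaQ	A	C	synonymous
Ara+1	40K-A	40000	3124208	yqiI	G	A	synonymous
Ara+1	40K-A	40000	3308106	yhcB	G	A	synonymous
Ara+1	40K-B	40000	3308106	yhcB	G	A	synonymous
Ara+1	40K-A	40000	3409316	yheS	T	G	synonymous
Ara+1	40K-B	40000	3409316	yheS	T	G	synonymous
Ara+1	40K-B	40000	3527027	livH	C	A	synonymous
Ara+1	40K-B	40000	3910606	yifB	T	G	synonymous
Ara+1	40K-A	40000	4133104	ppc	G	A	synonymous
Ara+1	40K-B	40000	4133104	ppc	G	A	synonymous
Ara+2	40K-A	40000	1083668	wrbA	C	T	synonymous
Ara+4	40K-A	40000	420328	cyoB	A	C	synonymous
Ara+4	40K-B	40000	420328	cyoB	A	C	synonymous
Ara+4	40K-A	40000	2772320	Iap	A	C	synonymous
Ara+4	40K-B	40000	2772320	Iap	A	C	synonymous
Ara+4	40K-A	40000	3061109	ECB_02854	G	A	synonymous
Ara+5	40K-A	40000	122591	ampE	T	A	synonymous
Ara+5	40K-B	40000	122591	ampE	T	A	synonymous
Ara+5	40K-A	40000	212865	ldcC	T	C	synonymous
Ara+5	40K-B	40000	212865	ldcC	T	C	synonymous
Ara+5	40K-A	40000	1317194	trpC	G	A	synonymous
Ara+5	40K-B	40000	1317194	trpC	G	A	synonymous
Ara+5	40K-A	40000	2009188	yoeF	G	T	synonymous
Ara+5	40K-B	40000	2009188	yoeF	G	T	synonymous
Ara+5	40K-A	40000	2251393	napA	G	A	synonymous
Ara+5	40K-B	40000	2251393	napA	G	A	synonymous
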