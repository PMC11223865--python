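# snvpam packaged Cas/PAM registry, v1
# columns: name, organism, uniprot_id, variant, source, subtype, pam, less_preferred (';'-joined), structures (';'-joined)
name	organism	uniprot_id	variant	source	subtype	pam	less_preferred	structures
SpCas9	S. pyogenes	Q99ZW2	-	natural	II-A	NGG	NAG;NGA	4UN3;5Y36;5FQ5
SpCas9-VQR	S. pyogenes	-	VQR	engineered	II-A	NGA	-	5B2R
SpCas9-VRER	S. pyogenes	-	VRER	engineered	II-A	NGCG	-	5B2T;5FW3
SpCas9-EQR	S. pyogenes	-	EQR	engineered	II-A	NGAG	-	5B2S;5FW2
SpCas9-NG	S. pyogenes	-	NG	engineered	II-A	NG	-	6AI6
SpCas9-NRRH	S. pyogenes	-	NRRH	engineered	II-A	NRRH	-	-
SpCas9-NRCH	S. pyogenes	-	NRCH	engineered	II-A	NRCH	-	-
SpCas9-NRTH	S. pyogenes	-	NRTH	engineered	II-A	NRTH	-	-
xCas9	S. pyogenes	-	xCas9	engineered	II-A	NGN	-	6K4P;6K4Q;6K4S;6K4U;6AEB;6AEG
SaCas9	S. aureus	J7RUA5	-	natural	II-A	NNGRRT	-	5AXW;5CZZ
SaCas9-KKH	S. aureus	-	KKH	engineered	II-A	NNNRRT	-	-
St1Cas9	S. thermophilus	Q03JI6	-	natural	II-A	NNRGAAW	NNGGAAW;NNGATAG;NNTCTTA;NNCAATA	-
St3Cas9	S. thermophilus	G3ECR1	-	natural	II-A	NGGNG	-	-
SpasCas9	S. pasteurianus	F5X275	-	natural	II-A	NNGTGA	-	-
TdCas9	T. denticola	Q73QW6	-	natural	II-A	NAAAAC	-	-
Nme1Cas9	N. meningitidis	C9X1G5	-	natural	II-C	NNNNGATT	-	6JDV;6KC8
Nme2Cas9	N. meningitidis	A1IQ68	-	natural	II-C	NHDTCCA	-	6JFU;6JE3
CjCas9	C. jejuni	Q0P897	-	natural	II-C	NNNVRYM	-	5X2H;5X2G
AceCas9	A. cellulolyticus	A0LWB3	-	natural	II-C	NNNCC	-	6WBR;6WC0
FnCas9	F. novicida	A0Q5Y3	-	natural	II-B	NGG	NAG;NGA	5B2O;5B2P
FnCas9-RHA	F. novicida	-	RHA	engineered	II-B	YG	-	5B2Q
FnCas12a	F. novicida	A0Q7Q2	-	natural	V-A	TTV	-	-
AsCas12a	Acidaminococcus sp.	U2UMQ6	-	natural	V-A	TTTN	VTTV;YCCA;TCTV;TTCV;GTTV;GCTV	5B43
AsCas12a-RVR	Acidaminococcus sp.	-	RVR	engineered	V-A	TATV	-	5XH6
AsCas12a-RR	Acidaminococcus sp.	-	RR	engineered	V-A	TYCV	-	5XH7
enAsCas12a-TGTV	Acidaminococcus sp.	-	TGTV	engineered	V-A	TGTV	-	-
enAsCas12a-VTTV	Acidaminococcus sp.	-	VTTV	engineered	V-A	VTTV	-	-
enAsCas12a-TTTT	Acidaminococcus sp.	-	TTTT	engineered	V-A	TTTT	-	-
enAsCas12a-TTCN	Acidaminococcus sp.	-	TTCN	engineered	V-A	TTCN	-	-
AsCas12a-RVRm	Acidaminococcus sp.	-	RVRm	engineered	V-A	TATG	-	-
LbCas12a	L. bacterium	A0A5S8WF58	-	natural	V-A	TTTN	TCTA;TCCA;CCCA	5XUS;5XUT;5XUU;5XUZ
MbCas12a	M. bovoculi	A0A3F3CDD6	-	natural	V	TTTN	-	-
AacCas12b	A. acidoterrestris	T0D7A2	-	natural	V-B	DTTD	-	-
BthCas12b	Brevibacillus sp.	A0A9X7XSH8	-	natural	V-B	ATTN	-	-
DpbCas12e	Deltaproteobacteria	A0A357BT59	-	natural	V-E	TTCN	-	-
Cas12e	Planctomycetes	A0A1G3BXR9	-	natural	V-E	TTCN	-	-
Cas14a1	uncultured archaeon	A0A482D308	-	natural	V-F	TTTR	YTCA	7L49;7C7L
Cas12c1	P. muris	A0A9X9ZA50	-	natural	V-C	TG	-	7VYX
Cas12c2	P. muris	-	-	natural	V-C	TN	-	7V94
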