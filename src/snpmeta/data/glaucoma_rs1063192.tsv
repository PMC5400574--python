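study_id	year	ethnicity	soc	country	genotyping_method	case_tt	case_tc	case_cc	ctrl_tt	ctrl_tc	ctrl_cc	hwe_reported
Abu-Amero2016	2016	Caucasian	HB	Saudi Arabia	PCR	53	32	2	58	31	5	Y
Ng2016	2016	Caucasian	PB	Australia	Unclear	941	1022	278	1004	1564	608	Y
Burdon2015	2015	Caucasian	PB	Australia	PCR	28	31	8	579	950	390	Y
Chen2015	2015	Asian	HB	China	Unclear	770	348	39	592	303	39	Y
Williams2015	2015	African	HB	South Africa	PCR	215	0	0	214	0	0	N
Philomenadin2015	2015	Asian	HB	India	PCR	56	35	6	220	131	20	Y
Mabuchi2015	2015	Asian	HB	Japan	PCR	301	113	11	115	66	10	Y
Micheal2014	2014	Asian	HB	Pakistan	PCR	270	206	37	127	89	17	Y
Liu2013	2013	African	PB	USA	Unclear	980	163	7	875	120	4	Y
Liu2013	2013	African	PB	USA	Unclear	483	0	0	591	2	0	N
Cao2012	2012	African	PB	USA	PCR	251	21	0	135	29	1	Y
Osman2012	2012	Asian	PB	Japan	PCR	962	391	40	4155	2156	280	Y
Osman2012	2012	Asian	PB	Japan	PCR	1267	486	47	4452	2425	330	Y
Dimasi2012	2012	Caucasian	PB	Australia	Unclear	348	408	120	274	430	169	Y
Takamoto2012	2012	Asian	HB	Japan	PCR	109	38	4	120	60	7	Y
Fan2011	2011	Caucasian	PB	Netherland	TaqMan	170	172	47	102	155	51	Y
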