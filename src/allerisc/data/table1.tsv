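cluster	protein	length	n_predicted_tmh	exp_aa_in_tmh	exp_aa_first60	prob_n_in	signal_length	signal_peptide	sp_probability	anchor_probability
I	CAM31909.1_kiwi_D8	157	0	0	0	0.14	70	no	0	0
I	AAB97141.1_apricot_Ar1	160	0	0	0	0.06	70	no	0	0
I	XP_004296886.1_rasberry_I1	159	0	0	0	0.04	70	no	0	0
I	ABG54495.1_raspberry_I1	137	0	0	0	0.06	70	no	0	0
I	CAJ29538.1_strawberry_A1	160	0	0	0	0.13	70	no	0	0
I	ABB78006.1_peach_P1	160	0	0	0	0.04	70	no	0	0
I	AAC02632.1_cherry_A1	160	0	0	0	0.04	70	no	0	0
I	CAA58646.1_apple_D1	159	0	0	0	0.06	70	no	0	0
I	AAC13315.1_pear_C1	159	0	0	0	0.04	70	no	0	0
II	AAK54835.1_pineapple_C1	131	0	0	0	0.3	70	no	0	0
II	sp|C0HL99.1_kiwi_D9	109	0	0	0	0.41	70	no	0	0
II	XP_004287490.1_stawberry_A4	131	0	0	0	0.35	70	no	0	0
II	AAW69549.1_melon_M2	131	0	0	0	0.25	70	no	0	0
II	AAK54834.1_banana_A1	131	0	0	0	0.3	70	no	0.01	0
II	AAD29414.1_apple_D4	61	0	0	0	0.25	70	no	0	0
II	AAD29411.1_cherry_A4	131	0	0	0	0.3	70	no	0	0
II	CAD37201.1_peach_P4	131	0	0	0	0.3	70	no	0	0
II	CAD10390.1_date-palm_D2	131	0	0	0	0.28	70	no	0.01	0
II	AAD29410.1_pear_C4	131	0	0	0	0.3	70	no	0	0
III	GFZ19186.1_kiwi_D10	115	0	1	1	0.22	70	yes	1	0
III	XP_009396870.1_banana_A3	119	0	13	13	0.37	70	yes	1	0
III	XP_007206159.1_peach_P3	117	1	17	17	0.8	70	yes	1	0
III	ADR66947.1_apricot_Ar3	117	1	17	17	0.8	70	yes	1	0
III	PQP98495.1_plum_D3	117	1	17	17	0.79	70	yes	1	0
III	AAF26449.1_cherry_A3	117	1	17	17	0.78	70	yes	1	0
III	AAF26451.1_pear_C3	115	1	18	18	0.52	70	yes	1	0
III	AAT80633.1_apple_D3	115	0	16	16	0.57	70	yes	1	0
III	CAC86258.1_strawberry_A3	117	1	21	21	0.8	70	yes	1	0
III	ABG54494.1_raspberry_I3	117	1	20	20	0.62	70	yes	1	0
III	AAO33394.1_grape_V1	119	0	15	15	0.53	70	yes	1	0
III	AHB19227.1_pomegranate_G1	120	0	11	11	0.44	70	yes	1	0
IV	PSR89527.1_kiwi_D7	559	0	10	10	0.46	70	yes	0.89	0.1
IV	XP_007199020.1_peach_P9	161	1	17	17	0.89	70	yes	0.99	0
IV	M5X16_peach_P10	401	0	13	13	0.54	70	yes	0.92	0.1
IV	BAC54964.1_kiwi_D6	185	1	18	18	0.83	70	yes	0.94	0.1
IV	ABB77213.1_kiwi_D12	462	0	0	0	0.01	70	yes	1	0
IV	AAC24001.1_pear_C5	308	0	0	0	0.05	70	no	0.01	0
IV	P84527.2_greenkiwi_D5	213	0	8	8	0.25	70	yes	1	0
IV	AAD32205.1_apricot_Ar5	168	0	0	0	0.1	70	no	0.01	0
IV	BAA06905.1_melon_M1	731	0	0	0	0	70	yes	0.97	0
IV	P85524.1_kiwi_D11_P	150	0	0	0	0.21	70	no	0	0
IV	AAR92223.1_greenkiwi_D4	116	1	16	16	0.29	70	yes	1	0
IV	ACV85695.1_papaya_P1	494	1	18	18	0.92	70	yes	0.52	0.2
IV	XP_008455060.1_melon_M3	116	1	21	21	0.85	70	yes	0.95	0
IV	CAC81811.1_banana_A2	318	0	0	0	0.02	70	yes	1	0
IV	CAB01591.1_pers_A1	326	0	15	14	0.66	70	yes	1	0
IV	AAB82772.2_banana_A5	340	0	14	13	0.66	70	yes	1	0
IV	ALQ56981.1_coconut_N1_P	490	1	20	19	0.97	70	yes	0.99	0
IV	XP_021820299.1_cherry_Av7	88	0	11	11	0.31	70	yes	1	0
IV	XP_016648029.1_peach_P7	88	0	11	11	0.31	70	yes	1	0
IV	CAI38795.2_greenkiwi_D2	225	1	19	19	0.85	70	yes	1	0
IV	XP_009406737.1_banana_A4	226	1	22	22	0.82	70	yes	1	0
IV	AAB38064.1_cherry_A2	245	1	21	21	0.92	70	yes	1	0
IV	AAC36740.1_apple_D2	245	0	0	0	0.1	70	yes	1	0
IV	ACE80959.1_peach_P2	246	1	18	18	0.77	70	yes	1	0
IV	BAA21849.1_pineapple_C2	351	1	16	16	0.88	70	yes	1	0
IV	CAA66378.1_papaya_P2	352	0	13	13	0.61	70	yes	0.99	0
IV	CAA34486.1_greenkiwi_D1	380	1	17	16	0.65	70	yes	0.95	0.1
IV	AAX40948.1_date_M1_1	330	0	4	4	0.21	70	yes	0.99	0
IV	G1UH28_pomegranate_G14	299	0	16	14	0.57	70	yes	1	0
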