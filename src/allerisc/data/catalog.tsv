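accession	label	species	cluster
CAM31909.1	kiwi_D8	kiwi	I
AAB97141.1	apricot_Ar1	apricot	I
XP_004296886.1	rasberry_I1	raspberry	I
ABG54495.1	raspberry_I1	raspberry	I
CAJ29538.1	strawberry_A1	strawberry	I
ABB78006.1	peach_P1	peach	I
AAC02632.1	cherry_A1	cherry	I
CAA58646.1	apple_D1	apple	I
AAC13315.1	pear_C1	pear	I
AAK54835.1	pineapple_C1	pineapple	II
C0HL99.1	kiwi_D9	kiwi	II
XP_004287490.1	stawberry_A4	strawberry	II
AAW69549.1	melon_M2	melon	II
AAK54834.1	banana_A1	banana	II
AAD29414.1	apple_D4	apple	II
AAD29411.1	cherry_A4	cherry	II
CAD37201.1	peach_P4	peach	II
CAD10390.1	date-palm_D2	date palm	II
AAD29410.1	pear_C4	pear	II
GFZ19186.1	kiwi_D10	kiwi	III
XP_009396870.1	banana_A3	banana	III
XP_007206159.1	peach_P3	peach	III
ADR66947.1	apricot_Ar3	apricot	III
PQP98495.1	plum_D3	plum	III
AAF26449.1	cherry_A3	cherry	III
AAF26451.1	pear_C3	pear	III
AAT80633.1	apple_D3	apple	III
CAC86258.1	strawberry_A3	strawberry	III
ABG54494.1	raspberry_I3	raspberry	III
AAO33394.1	grape_V1	grape	III
AHB19227.1	pomegranate_G1	pomegranate	III
PSR89527.1	kiwi_D7	kiwi	IV
XP_007199020.1	peach_P9	peach	IV
M5X16	peach_P10	peach	IV
BAC54964.1	kiwi_D6	kiwi	IV
ABB77213.1	kiwi_D12	kiwi	IV
AAC24001.1	pear_C5	pear	IV
P84527.2	greenkiwi_D5	green kiwi	IV
AAD32205.1	apricot_Ar5	apricot	IV
BAA06905.1	melon_M1	melon	IV
P85524.1	kiwi_D11_P	kiwi	IV
AAR92223.1	greenkiwi_D4	green kiwi	IV
ACV85695.1	papaya_P1	papaya	IV
XP_008455060.1	melon_M3	melon	IV
CAC81811.1	banana_A2	banana	IV
CAB01591.1	pers_A1	avocado	IV
AAB82772.2	banana_A5	banana	IV
ALQ56981.1	coconut_N1_P	coconut	IV
XP_021820299.1	cherry_Av7	cherry	IV
XP_016648029.1	peach_P7	peach	IV
CAI38795.2	greenkiwi_D2	green kiwi	IV
XP_009406737.1	banana_A4	banana	IV
AAB38064.1	cherry_A2	cherry	IV
AAC36740.1	apple_D2	apple	IV
ACE80959.1	peach_P2	peach	IV
BAA21849.1	pineapple_C2	pineapple	IV
CAA66378.1	papaya_P2	papaya	IV
CAA34486.1	greenkiwi_D1	green kiwi	IV
AAX40948.1	date_M1_1	date palm	IV
G1UH28	pomegranate_G14	pomegranate	IV
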