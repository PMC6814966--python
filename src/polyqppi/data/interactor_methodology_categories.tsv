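gene_symbol	uniprot	category
ILVBL	A1L0T0	expanded_in_both
EIF3F	O00303	expanded_in_both
TRIM38	O00635	expanded_in_both
TP53I11	O14683	wt_2_expanded_1
MAGEB2	O15479	expanded_in_both
RBFOX2	O43251	expanded_in_both
EIF1B	O60739	wt_in_both
CXorf27	O75409	wt_2_expanded_1
STAM2	O75886	expanded_in_both
PIAS1	O75925	expanded_in_both
TTRAP	O95551	expanded_in_both
ASNS	P08243	expanded_in_both
ESRRA	P11474	expanded_in_both
NCAM1	P13591	expanded_in_both
FOSL1	P15407	expanded_in_both
OTX2	P32243	expanded_in_both
MSX2	P35548	wt_1_expanded_2
CHRNA7	P36544	expanded_in_both
ETV4	P43268	expanded_in_both
CRK	P46108	expanded_in_both
CRIP2	P52943	wt_1_expanded_2
TCTA	P57738	wt_2_expanded_1
YWHAE	P62258	expanded_in_both
PSPH	P78330	wt_1_expanded_2
BASP1	P80723	expanded_in_both
CREM	Q03060	wt_1_expanded_2
ARID5A	Q03989	expanded_in_both
PPAT	Q06203	expanded_in_both
CAMK2B	Q13554	expanded_in_both
RAPGEF1	Q13905	expanded_in_both
KIF22	Q14807	expanded_in_both
LASP1	Q14847	expanded_in_both
TOMM20	Q15388	wt_in_both
DIXDC1	Q155Q3	expanded_in_both
SF1	Q15637	expanded_in_both
IMMT	Q16891	expanded_in_both
CRY2	Q49AN0	wt_in_both
C2orf27B	Q580R0	expanded_in_both
RBM26	Q5T8P6	wt_in_both
SV2A	Q7L0J3	wt_1_expanded_2
DHX37	Q8IY37	expanded_in_both
DHRSX	Q8N5I4	expanded_in_both
MAGEB6	Q8N7X4	expanded_in_both
ZSCAN1	Q8NBB4	expanded_in_both
GATAD1	Q8WUU5	expanded_in_both
HNRPLL	Q8WVV9	expanded_in_both
FAR1	Q8WVX9	expanded_in_both
BAALC	Q8WXS3	expanded_in_both
TSC1	Q92574	expanded_in_both
FAM46B	Q96A09	expanded_in_both
WBSCR16	Q96I51	expanded_in_both
FAM46A	Q96IP4	wt_1_expanded_1_and_2
ZC3H10	Q96K80	expanded_in_both
MAGEB18	Q96M61	expanded_in_both
UHRF2	Q96PU4	expanded_in_both
QKI	Q96PU8	expanded_in_both
KCTD15	Q96SI1	expanded_in_both
LITAF	Q99732	wt_in_both
MLST8	Q9BVC4	expanded_in_both
MCART1	Q9H1U9	expanded_in_both
C16orf5	Q9H305	expanded_in_both
LPAR2	Q9HBW0	expanded_in_both
HEYL	Q9NQ87	expanded_in_both
SLC6A13	Q9NSD5	expanded_in_both
SEMA4G	Q9NTN9	wt_in_both
HEY2	Q9UBP5	expanded_in_both
ADD3	Q9UEY8	expanded_in_both
PLEKHB1	Q9UF11	wt_1_expanded_2
GGA2	Q9UJY4	wt_in_both
TMX2	Q9Y320	expanded_in_both
RAI2	Q9Y5P3	wt_2_expanded_1
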