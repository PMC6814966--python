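gene_symbol	uniprot	predicted_approach2	experimental	discordant
ILVBL	A1L0T0	expanded	wt	0
EIF3F	O00303	expanded	wt	0
TRIM38	O00635	expanded	expanded	0
TP53I11	O14683	wt	expanded	1
MAGEB2	O15479	expanded	wt	0
RBM9	O43251	expanded	expanded	0
EIF1B	O60739	wt	expanded	0
CXorf27	O75409	wt	wt	1
STAM2	O75886	expanded	no_preference	0
PIAS1	O75925	expanded	expanded	0
TTRAP	O95551	expanded	expanded	0
ASNS	P08243	expanded	wt	0
ESRRA	P11474	expanded	expanded	0
NCAM1	P13591	expanded	expanded	0
FOSL1	P15407	expanded	no_preference	0
OTX2	P32243	expanded	expanded	0
MSX2	P35548	expanded	expanded	1
CHRNA7	P36544	expanded	no_preference	0
ETV4	P43268	expanded	wt	0
CRK	P46108	expanded	expanded	0
CRIP2	P52943	expanded	expanded	1
TCTA	P57738	wt	expanded	1
YWHAE	P62258	expanded	expanded	0
PSPH	P78330	expanded	expanded	1
BASP1	P80723	expanded	expanded	0
CREM	Q03060	expanded	expanded	1
ARID5A	Q03989	expanded	no_preference	0
PPAT	Q06203	expanded	expanded	0
CAMK2B	Q13554	expanded	wt	0
RAPGEF1	Q13905	expanded	expanded	0
KIF22	Q14807	expanded	expanded	0
LASP1	Q14847	expanded	no_preference	0
TOMM20	Q15388	wt	wt	0
DIXDC1	Q155Q3	expanded	wt	0
SF1	Q15637	expanded	expanded	0
IMMT	Q16891	expanded	expanded	0
CRY2	Q49AN0	wt	expanded	0
C2orf27B	Q580R0	expanded	expanded	0
RBM26	Q5T8P6	wt	expanded	0
SV2A	Q7L0J3	expanded	expanded	1
DHX37	Q8IY37	expanded	wt	0
DHRSX	Q8N5I4	expanded	expanded	0
MAGEB6	Q8N7X4	expanded	wt	0
ZSCAN1	Q8NBB4	expanded	expanded	0
GATAD1	Q8WUU5	expanded	expanded	0
HNRPLL	Q8WVV9	expanded	expanded	0
FAR1	Q8WVX9	expanded	expanded	0
BAALC	Q8WXS3	expanded	expanded	0
TSC1	Q92574	expanded	no_preference	0
FAM46B	Q96A09	expanded	expanded	0
WBSCR16	Q96I51	expanded	wt	0
FAM46A	Q96IP4	expanded	expanded	1
ZC3H10	Q96K80	expanded	expanded	0
MAGEB18	Q96M61	expanded	wt	0
UHRF2	Q96PU4	expanded	expanded	0
QKI	Q96PU8	expanded	expanded	0
KCTD15	Q96SI1	expanded	expanded	0
LITAF	Q99732	wt	expanded	0
MLST8	Q9BVC4	expanded	no_preference	0
MCART1	Q9H1U9	expanded	expanded	0
C16orf5	Q9H305	expanded	expanded	0
LPAR2	Q9HBW0	expanded	expanded	0
HEYL	Q9NQ87	expanded	wt	0
SLC6A13	Q9NSD5	expanded	expanded	0
SEMA4G	Q9NTN9	wt	expanded	0
HEY2	Q9UBP5	expanded	expanded	0
ADD3	Q9UEY8	expanded	wt	0
PLEKHB1	Q9UF11	expanded	expanded	1
GGA2	Q9UJY4	wt	wt	0
TMX2	Q9Y320	expanded	expanded	0
RAI2	Q9Y5P3	wt	expanded	1
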