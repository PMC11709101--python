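gene	direction
CDKN1A	up
CDKN2A	up
CDKN2B	up
CDKN1B	up
TP53	up
SERPINE1	up
IGFBP3	up
IGFBP4	up
IGFBP5	up
IGFBP7	up
IL6	up
IL1A	up
IL1B	up
CXCL8	up
CXCL1	up
CXCL2	up
CCL2	up
CCL20	up
TNF	up
GDF15	up
TIMP1	up
TIMP2	up
MMP1	up
MMP3	up
MMP9	up
MMP12	up
PLAU	up
PLAUR	up
ICAM1	up
TNFRSF10C	up
TNFRSF1B	up
FAS	up
BCL2	up
BCL2L1	up
BCL2L2	up
MCL1	up
BAX	up
GLB1	up
SERPINB2	up
CCND1	up
CCND2	up
E2F7	up
MDM2	up
TGFB1	up
TGFB2	up
NFKB1	up
RELA	up
JUN	up
FOS	up
EGR1	up
GADD45A	up
GADD45B	up
HMGB1	up
STAT1	up
STAT3	up
SQSTM1	up
LMNA	up
B2M	up
VIM	up
FN1	up
SPARC	up
THBS1	up
CTGF	up
CYR61	up
AREG	up
EREG	up
HBEGF	up
FGF2	up
FGF7	up
VEGFA	up
ANGPTL4	up
INHBA	up
CLU	up
CST3	up
LGALS3	up
S100A8	up
S100A9	up
SOD1	up
SOD2	up
CAT	up
GPX1	up
HMOX1	up
NQO1	up
TXN	up
PRDX1	up
FTL	up
FTH1	up
SLC7A11	up
ACSL4	up
GPX4	up
ALOX15	up
SSK001	up
SSK002	up
SSK003	up
SSK004	up
SSK005	up
SSK006	up
SSK007	up
SSK008	up
SSK009	up
SSK010	up
SSK011	up
SSK012	up
SSK013	up
SSK014	up
SSK015	up
SSK016	up
SSK017	up
SSK018	up
SSK019	up
SSK020	up
SSK021	up
SSK022	up
SSK023	up
SSK024	up
SSK025	up
SSK026	up
SSK027	up
SSK028	up
SSK029	up
SSK030	up
SSK031	up
SSK032	up
SSK033	up
SSK034	up
SSK035	up
SSK036	up
SSK037	up
SSK038	up
SSK039	up
SSK040	up
SSK041	up
SSK042	up
SSK043	up
SSK044	up
SSK045	up
SSK046	up
SSK047	up
SSK048	up
SSK049	up
SSK050	up
SSK051	up
SSK052	up
SSK053	up
SSK054	up
SSK055	up
SSK056	up
SSK057	up
SSK058	up
SSK059	up
SSK060	up
SSK061	up
SSK062	up
SSK063	up
SSK064	up
SSK065	up
SSK066	up
SSK067	up
SSK068	up
SSK069	up
SSK070	up
SSK071	up
SSK072	up
SSK073	up
LMNB1	down
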