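# gene	pathway
# Morphogenic processes/pathways of lip and palate development.
# The PLEKHA5 and CREBBP assignments are editable data, not code.
PTCH1	HH
GLI2	HH
GLI3	HH
SHH	HH
SMO	HH
IRF6	epithelial-related
TP63	epithelial-related
GRHL3	epithelial-related
CTNND1	epithelial-related
CDH1	epithelial-related
ESRP2	epithelial-related
SPECC1L	epithelial-related
ARHGAP29	epithelial-related
PLEKHA5	epithelial-related
CREBBP	TGF-beta
TGFB3	TGF-beta
TGFBR1	TGF-beta
TGFBR2	TGF-beta
SMAD4	TGF-beta
BMP2	TGF-beta
BMP4	TGF-beta
NOG	TGF-beta
FZD6	WNT
WNT3	WNT
WNT9B	WNT
LRP6	WNT
PAX7	WNT
VAX1	WNT
FGF8	FGF
FGFR1	FGF
FGFR2	FGF
SPRY2	FGF
MSX1	other
PAX9	other
SATB2	other
SOX9	other
RUNX2	other
TBX22	other
DLX4	other
TFAP2A	other
FOXE1	other
EFNB1	other
CHD7	other
KMT2D	other
COL2A1	other
ECPAS	proteasome-associated
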