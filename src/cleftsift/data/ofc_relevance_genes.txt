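# Curated gene symbols implicated in orofacial clefting or craniofacial
# development. One symbol per line. This list is a data input to the
# phenotype-relevance screen; edit or replace it to change the screen.
ARHGAP29
BMP2
BMP4
CDH1
CHD7
COL2A1
CREBBP
CTNND1
DLX4
ECPAS
EFNB1
ESRP2
FGF8
FGFR1
FGFR2
FOXE1
FZD6
GLI2
GLI3
GRHL3
IRF6
KMT2D
LRP6
MSX1
NOG
PAX7
PAX9
PLEKHA5
PTCH1
RUNX2
SATB2
SHH
SMAD4
SMO
SOX9
SPECC1L
SPRY2
TBX22
TFAP2A
TGFB3
TGFBR1
TGFBR2
TP63
VAX1
WNT3
WNT9B
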