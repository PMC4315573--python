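# Synthetic stand-in for a 182-gene ASD panel (SFARI-style).
# Real ASD-associated gene symbols; not the published supplementary list.
ADNP
ADSL
AFF2
AGAP1
AHI1
ALDH5A1
ANK2
ANK3
ANKRD11
AP1S2
ARID1B
ARX
ASH1L
ASXL3
ATRX
AUTS2
AVPR1A
BCKDK
BCL11A
BRAF
CACNA1C
CACNA1D
CACNA1E
CACNA1F
CACNA1G
CACNA1H
CACNA2D3
CACNB2
CADPS2
CASK
CC2D1A
CDKL5
CHD2
CHD7
CHD8
CIC
CNTN4
CNTN5
CNTN6
CNTNAP2
CNTNAP4
CREBBP
CTCF
CTNNB1
CUL3
CYFIP1
DDX3X
DEAF1
DHCR7
DIP2A
DISC1
DLG3
DLGAP2
DMD
DMPK
DNMT3A
DPP6
DPYD
DSCAM
DYRK1A
EHMT1
EIF4E
EN2
EP300
EXT1
FMR1
FOXG1
FOXP1
FOXP2
GABRA3
GABRB2
GABRB3
GABRG3
GATM
GIGYF2
GRIA3
GRID2
GRIK2
GRIN1
GRIN2A
GRIN2B
GRM5
HERC2
HNRNPH2
HNRNPU
HOXA1
HRAS
IL1RAPL1
IQSEC2
KANSL1
KATNAL2
KCNB1
KCNJ10
KCNMA1
KCNQ2
KCNQ3
KDM5B
KDM5C
KDM6B
KMT2A
KMT2C
KMT5B
L1CAM
LAMC3
LRFN5
MAGEL2
MBD5
MBOAT7
MECP2
MED12
MED13L
MEF2C
MET
MYT1L
NAA15
NBEA
NCKAP1
NF1
NIPBL
NLGN1
NLGN2
NLGN3
NLGN4X
NR3C2
NRXN1
NRXN2
NRXN3
NSD1
NTNG1
NTNG2
OPHN1
PAX6
PCDH10
PCDH19
PHF3
PHF8
POGZ
POMGNT1
PTCHD1
PTEN
PTPN11
RAB39B
RAI1
RBFOX1
RELN
RERE
RIMS1
RPL10
SCN1A
SCN2A
SCN8A
SETD2
SETD5
SETBP1
SHANK1
SHANK2
SHANK3
SLC6A4
SLC9A6
SLC9A9
SMARCC2
SON
SOX5
SPAST
SRCAP
ST7
STXBP1
SYN1
SYN2
SYNGAP1
TAOK2
TBCK
TBL1XR1
TBR1
TCF4
TCF7L2
TRIO
TRIP12
TSC1
TSC2
TSHZ3
UBE3A
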