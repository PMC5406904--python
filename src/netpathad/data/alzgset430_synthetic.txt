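# SYNTHETIC stand-in for the 430-gene Alzheimer's disease seed list (Alzgset).
# The first 204 symbols are the disease-set members actually printed in the
# source publication's main text and pathway table; the SYNAD* symbols are
# synthetic placeholders padding the list to the published size of 430.
A2M
ABCA1
ABCA2
ABCA7
ABCC2
ABCG1
ABCG2
ADRA2B
ADRB1
ADRB2
ADRB3
ALOX5
APH1A
APH1B
APOA1
APOA4
APOC1
APOC2
APOC4
APOD
APOE
APP
ATXN1
BDNF
C4A
C4B
CAMK2D
CARD8
CCL2
CCL3
CCR2
CD14
CD33
CD36
CD44
CDK1
CDK5
CDK5R1
CDKN2A
CFH
CHAT
CHRFAM7A
CHRNA3
CHRNA4
CHRNA7
CHRNB2
CLOCK
COL11A1
COMT
COX10
COX15
CR1
CTSS
CXCL8
CYP19A1
CYP2D6
DBH
DRD4
DYRK1A
EFNA5
EIF4EBP1
ESR1
ESR2
EXOC2
F13A1
FAS
FCER1G
FGF1
FSHR
GAB2
GAPDH
GNA11
GNB3
GOLM1
GPX1
GRIN2B
GSK3B
GSTM1
GSTM3
GSTO1
GSTO2
GSTP1
GSTT1
HLA-A
HLA-DQB1
HLA-DRA
HLA-DRB1
HLA-DRB5
HMOX1
HSD11B1
HSPA5
HTR2A
HTR6
ICAM1
IGF1
IL10
IL12A
IL12B
IL18
IL1A
IL1B
IL1RN
IL23R
IL4
IL6
IL6R
INPP5D
INS
IRS1
KCNJ6
LCK
LDLR
LHCGR
LPL
MAGI2
MAOA
MAPK8IP1
MAPT
MBL2
MEF2A
MEF2C
MEFV
MME
MMP3
MPO
MT-ATP6
MT-ATP8
MT-CO1
MT-CO2
MT-CO3
MT-CYB
MT-ND1
MT-ND2
MT-ND3
MT-ND4
MT-ND4L
MT-ND5
MT-ND6
MT-TG
MT-TH
MT-TL2
MT-TQ
MT-TR
MT-TS2
MT-TT
MTHFR
MYLK
NCSTN
NGF
NGFR
NLRC3
NLRP1
NLRP3
NOS1
NOS3
NTF3
NTRK1
NTRK2
OLR1
PARP1
PCK1
PIK3R1
PLA2G3
PLA2G4A
PLAU
PNMT
PPARA
PPARG
PPP2R2B
PSEN1
PSEN2
PSENEN
PTGS2
PTK2B
RAB7A
RELN
RPS6KB2
RXRA
SERPINA1
SLC19A1
SLC24A4
SLC2A14
SLC2A9
SLC6A3
SLC6A4
SOD1
SOD2
SOS2
SP1
STAR
TAP2
TF
TGFB1
TLR2
TLR4
TLR9
TNF
TP53
TP73
TRAF2
TREM2
UBE2I
VEGFA
YWHAQ
SYNAD001
SYNAD002
SYNAD003
SYNAD004
SYNAD005
SYNAD006
SYNAD007
SYNAD008
SYNAD009
SYNAD010
SYNAD011
SYNAD012
SYNAD013
SYNAD014
SYNAD015
SYNAD016
SYNAD017
SYNAD018
SYNAD019
SYNAD020
SYNAD021
SYNAD022
SYNAD023
SYNAD024
SYNAD025
SYNAD026
SYNAD027
SYNAD028
SYNAD029
SYNAD030
SYNAD031
SYNAD032
SYNAD033
SYNAD034
SYNAD035
SYNAD036
SYNAD037
SYNAD038
SYNAD039
SYNAD040
SYNAD041
SYNAD042
SYNAD043
SYNAD044
SYNAD045
SYNAD046
SYNAD047
SYNAD048
SYNAD049
SYNAD050
SYNAD051
SYNAD052
SYNAD053
SYNAD054
SYNAD055
SYNAD056
SYNAD057
SYNAD058
SYNAD059
SYNAD060
SYNAD061
SYNAD062
SYNAD063
SYNAD064
SYNAD065
SYNAD066
SYNAD067
SYNAD068
SYNAD069
SYNAD070
SYNAD071
SYNAD072
SYNAD073
SYNAD074
SYNAD075
SYNAD076
SYNAD077
SYNAD078
SYNAD079
SYNAD080
SYNAD081
SYNAD082
SYNAD083
SYNAD084
SYNAD085
SYNAD086
SYNAD087
SYNAD088
SYNAD089
SYNAD090
SYNAD091
SYNAD092
SYNAD093
SYNAD094
SYNAD095
SYNAD096
SYNAD097
SYNAD098
SYNAD099
SYNAD100
SYNAD101
SYNAD102
SYNAD103
SYNAD104
SYNAD105
SYNAD106
SYNAD107
SYNAD108
SYNAD109
SYNAD110
SYNAD111
SYNAD112
SYNAD113
SYNAD114
SYNAD115
SYNAD116
SYNAD117
SYNAD118
SYNAD119
SYNAD120
SYNAD121
SYNAD122
SYNAD123
SYNAD124
SYNAD125
SYNAD126
SYNAD127
SYNAD128
SYNAD129
SYNAD130
SYNAD131
SYNAD132
SYNAD133
SYNAD134
SYNAD135
SYNAD136
SYNAD137
SYNAD138
SYNAD139
SYNAD140
SYNAD141
SYNAD142
SYNAD143
SYNAD144
SYNAD145
SYNAD146
SYNAD147
SYNAD148
SYNAD149
SYNAD150
SYNAD151
SYNAD152
SYNAD153
SYNAD154
SYNAD155
SYNAD156
SYNAD157
SYNAD158
SYNAD159
SYNAD160
SYNAD161
SYNAD162
SYNAD163
SYNAD164
SYNAD165
SYNAD166
SYNAD167
SYNAD168
SYNAD169
SYNAD170
SYNAD171
SYNAD172
SYNAD173
SYNAD174
SYNAD175
SYNAD176
SYNAD177
SYNAD178
SYNAD179
SYNAD180
SYNAD181
SYNAD182
SYNAD183
SYNAD184
SYNAD185
SYNAD186
SYNAD187
SYNAD188
SYNAD189
SYNAD190
SYNAD191
SYNAD192
SYNAD193
SYNAD194
SYNAD195
SYNAD196
SYNAD197
SYNAD198
SYNAD199
SYNAD200
SYNAD201
SYNAD202
SYNAD203
SYNAD204
SYNAD205
SYNAD206
SYNAD207
SYNAD208
SYNAD209
SYNAD210
SYNAD211
SYNAD212
SYNAD213
SYNAD214
SYNAD215
SYNAD216
SYNAD217
SYNAD218
SYNAD219
SYNAD220
SYNAD221
SYNAD222
SYNAD223
SYNAD224
SYNAD225
SYNAD226
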