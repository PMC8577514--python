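gene_id	frequency
NKAIN1	100
UBE2E2	99
F13A1	92
RNF149	81
PLAUR	80
TNFAIP8	63
PIPOX	59
CTSC	58
SLC2A10	56
MTSS1	51
FAM57B	46
LRRC16A	40
GNA15	38
EGFR	35
FGFR3	31
PLCXD2	30
DYRK3	30
PAX6	28
HEPACAM	27
ITGA7	25
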