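alias	canonical
ND1	nad1
ND2	nad2
ND3	nad3
ND4	nad4
ND4L	nad4l
ND5	nad5
ND6	nad6
NADH1	nad1
NADH2	nad2
NADH3	nad3
NADH4	nad4
NADH4L	nad4l
NADH5	nad5
NADH6	nad6
COX1	cox1
COX2	cox2
COX3	cox3
COI	cox1
COII	cox2
COIII	cox3
CO1	cox1
CO2	cox2
CO3	cox3
COXI	cox1
COXII	cox2
COXIII	cox3
CYTB	cob
CYB	cob
COB	cob
ATP6	atp6
ATP8	atp8
ATPASE6	atp6
ATPASE8	atp8
12S	rrnS
16S	rrnL
12S RRNA	rrnS
16S RRNA	rrnL
12S RIBOSOMAL RNA	rrnS
16S RIBOSOMAL RNA	rrnL
S-RRNA	rrnS
L-RRNA	rrnL
RRN12	rrnS
RRN16	rrnL
SMALL SUBUNIT RIBOSOMAL RNA	rrnS
LARGE SUBUNIT RIBOSOMAL RNA	rrnL
D-LOOP	CR
D_LOOP	CR
CONTROL REGION	CR
CONTROL_REGION	CR
OL	OL
ORIGIN OF L-STRAND REPLICATION	OL
ORIGIN_L	OL
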