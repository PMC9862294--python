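label	area_id
FP1	2
FPZ	3
FP2	1
AF7	2
AF3	2
AFZ	3
AF4	1
AF8	1
F7	2
F5	2
F3	2
F1	2
FZ	3
F2	1
F4	1
F6	1
F8	1
FC5	5
FC3	5
FC1	5
FCZ	6
FC2	4
FC4	4
FC6	4
C5	5
C3	5
C1	5
CZ	6
C2	4
C4	4
C6	4
T7	5
T8	4
CP5	5
CP3	5
CP1	5
CPZ	6
CP2	4
CP4	4
CP6	4
TP7	5
TP8	4
P9	5
P7	5
P5	5
P3	5
P1	5
PZ	6
P2	4
P4	4
P6	4
P8	4
PO7	8
PO3	8
POZ	9
PO4	7
PO8	7
O1	8
OZ	9
O2	7
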