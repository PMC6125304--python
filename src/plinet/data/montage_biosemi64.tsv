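label	region	hemisphere
Fp1	frontal	left
AF7	frontal	left
AF3	frontal	left
F1	frontal	left
F3	frontal	left
F5	frontal	left
F7	frontal	left
FT7	temporal	left
FC5	central	left
FC3	central	left
FC1	central	left
C1	central	left
C3	central	left
C5	central	left
T7	temporal	left
TP7	temporal	left
CP5	central	left
CP3	central	left
CP1	central	left
P1	parieto-occipital	left
P3	parieto-occipital	left
P5	parieto-occipital	left
P7	parieto-occipital	left
P9	parieto-occipital	left
PO7	parieto-occipital	left
PO3	parieto-occipital	left
O1	parieto-occipital	left
Iz	none	midline
Oz	none	midline
POz	none	midline
Pz	none	midline
CPz	none	midline
Fpz	none	midline
Fp2	frontal	right
AF8	frontal	right
AF4	frontal	right
AFz	none	midline
Fz	none	midline
F2	frontal	right
F4	frontal	right
F6	frontal	right
F8	frontal	right
FT8	temporal	right
FC6	central	right
FC4	central	right
FC2	central	right
FCz	none	midline
Cz	none	midline
C2	central	right
C4	central	right
C6	central	right
T8	temporal	right
TP8	temporal	right
CP6	central	right
CP4	central	right
CP2	central	right
P2	parieto-occipital	right
P4	parieto-occipital	right
P6	parieto-occipital	right
P8	parieto-occipital	right
P10	parieto-occipital	right
PO8	parieto-occipital	right
PO4	parieto-occipital	right
O2	parieto-occipital	right
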