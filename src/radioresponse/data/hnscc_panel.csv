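cell_line,sf2,sf35,plating_efficiency,site
584A2,0.45,0.119,0.03,Larynx
CAL-27,0.459,0.248,0.07,Oral cavity
FADU,0.622,0.346,0.44,Hypopharynx
HN30,0.476,0.179,0.38,Pharynx
HN31,0.542,0.265,0.11,LN (HN30)
HN4,0.652,0.307,0.15,REC (larynx)
HN5,0.709,0.414,0.65,REC (oral cavity)
JHU011,0.447,0.19,0.1,REC (larynx)
JHU022,0.442,0.188,0.16,LN (larynx)
JHU029,0.482,0.196,0.25,Larynx
MDA1386LN,0.359,0.117,0.2,LN (MDA1386TU)
MDA1386TU,0.574,0.248,0.08,Hypopharynx
MDA686LN,0.617,0.319,0.02,LN (MDA686TU)
MDA686TU,0.624,0.339,0.08,Oropharynx
MDA886LN,0.342,0.131,0.03,LN (larynx)
OSC19,0.502,0.241,0.03,LN (oral cavity)
PCI13,0.522,0.31,0.03,Oral cavity
PCI-15A,0.342,0.108,0.08,Hypopharynx
PCI-15B,0.392,0.095,0.13,LN (PCI-15A)
PJ34,0.507,0.263,0.14,Oral cavity
SCC15,0.456,0.183,0.07,Oral cavity
SCC25,0.529,0.232,0.09,Oral cavity
SCC4,0.667,0.362,0.24,Oral cavity
SCC61,0.74,0.465,0.64,Oral cavity
SCC9,0.73,0.44,0.28,Oral cavity
Sqccy1,0.688,0.345,0.81,Oral cavity
TR146,0.554,0.256,0.09,REC (oral cavity)
Tul38,0.575,0.332,0.12,Oral cavity
UMSCC1,0.671,0.358,0.58,REC (oral cavity)
UMSCC11A,0.473,0.225,0.02,Larynx
UMSCC14B,0.449,0.152,0.35,REC (UMSCC14A)
UMSCC17A,0.232,0.056,0.14,Larynx
UMSCC17B,0.415,0.168,0.26,EXT (UMSCC17A)
UMSCC22A,0.473,0.176,0.12,Hypopharynx
UMSCC22B,0.434,0.113,0.07,LN (UMSCC22A)
UMSCC25,0.656,0.372,0.47,LN (larynx)
UMSCC47,0.259,0.075,0.09,Oral cavity
UMSCC4,0.63,0.342,0.2,Oropharynx
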