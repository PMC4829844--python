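marker,Tumor Tissue,MUG-CC1,MUG-CC1 LCL
D3S1358,"16,18",16,"16,18"
TH01,9.3,9.3,9.3
D21S11,"28,30",28,"28,30"
D18S51,12,12,12
Penta E,"10,13",10,"10,13"
D5S818,"11,12","11,12","11,12"
D13S317,"12,13","12,13","12,13"
D7S820,"8,11","8,11","8,11"
D16S539,"9,14","9,14","9,14"
CSF1PO,11,11,11
Penta D,"10,13",13,"10,13"
AMEL,"X,Y",X,"X,Y"
vWA,"16,18","16,18","16,18"
D8S1179,"13,15","13,15","13,15"
TPOX,"8,11","8,11","8,11"
FGA,23,23,23
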