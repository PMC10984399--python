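type,treatment,isoline,population,blocks,generation
fog,control_20C,6,K28,b1;b2,165
fog,control_20C,6,K60,b1;b2;b7;b8,166
fog,control_20C,8,K25,b3;b4,165
fog,control_20C,8,K12,b3;b4,143
fog,control_20C,8,K02,b3;b4,165
fog,control_20C,8,K54,b3;b4,164
fog,control_20C,9,K21,b5;b6,165
fog,control_20C,9,K40,b5;b6,96
fog,elevated_24C,6,E01,b7;b8,115
fog,elevated_24C,6,E02,b1;b2,106
fog,elevated_24C,6,E03,b7;b8,114
fog,elevated_24C,6,E05,b1;b2,145
fog,elevated_24C,6,E06,b1;b2,145
fog,elevated_24C,6,E08,b1;b2,145
fog,elevated_24C,6,E09,b1;b2,145
fog,elevated_24C,6,E12,b7;b8,143
fog,elevated_24C,8,E17,b3;b4,144
fog,elevated_24C,8,E13,b3;b4,110
fog,elevated_24C,8,E14,b3;b4,116
fog,elevated_24C,9,E34,b5;b6,112
wt,control_20C,6,K11,b1;b2;b7;b8,106
wt,control_20C,6,K32,b1;b2;b7;b8,106
wt,control_20C,8,K16,b3;b4,106
wt,control_20C,8,K37,b3;b4,106
wt,control_20C,8,K57,b3;b4,106
wt,control_20C,9,K03,b5;b6,106
wt,control_20C,9,K43,b5;b6,106
wt,elevated_24C,6,E73,b1;b2;b7;b8,146
wt,elevated_24C,6,E74,b1;b2;b7;b8,112
wt,elevated_24C,6,E75,b1;b2,112
wt,elevated_24C,8,E86,b3;b4,112
wt,elevated_24C,8,E87,b3;b4,112
wt,elevated_24C,9,E97,b5;b6,112
wt,elevated_24C,9,E98,b5;b6,112
wt,elevated_24C,9,E99,b5;b6,112
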