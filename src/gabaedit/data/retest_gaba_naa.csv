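roi,subject,crlb_pct_scan1,crlb_pct_scan2,gaba_naa_scan1,gaba_naa_scan2,cv_pct_printed
ACC,1,7,7,0.106,0.100,4.1
ACC,2,10,13,0.082,0.082,0.0
ACC,3,10,9,0.098,0.102,4.5
ACC,4,10,7,0.099,0.108,6.1
ACC,5,7,7,0.085,0.081,3.4
RCaud,1,15,16,0.081,0.105,18.2
RCaud,2,9,15,0.156,0.119,19.0
RCaud,3,17,12,0.127,0.110,10.1
RCaud,4,21,12,0.098,0.140,25.0
RCaud,5,14,8,0.127,0.151,12.2
LSTG,1,8,6,0.128,0.144,8.3
LSTG,2,8,6,0.091,0.099,6.0
LSTG,3,7,7,0.083,0.075,7.2
LSTG,4,10,13,0.108,0.103,3.4
LSTG,5,6,7,0.104,0.112,5.2
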