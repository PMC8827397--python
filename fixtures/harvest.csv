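year,hi
1994,0.14904584489338546
2000,0.07479659609526979
2010,0.18591379734830266
2016,0.18909031980958485
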