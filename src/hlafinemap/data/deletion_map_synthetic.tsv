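# SYNTHETIC default HLA-C allele -> rs67384697 (HLA-C 3'UTR G/del) lookup.
# C*06:02 -> del is grounded in the reported complete LD (D' = 1) between
# C*06:02 and the deletion; the remaining assignments are synthetic defaults
# for testing and should be replaced with a curated table for real analyses.
allele	state
C*01:02	G
C*02:02	del
C*03:04	G
C*04:01	del
C*05:01	del
C*06:02	del
C*07:01	G
C*07:02	G
C*12:03	del
C*15:02	del
C*16:01	G
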