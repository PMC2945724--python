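; 3-Lossless-10-24p: three weight-10 position-restricted seeds, 24
; positions in total, certified lossless for 1 indel + 1 SNP,
; 1 indel + 1 reading error, 2 SNPs, or 1 SNP + 2 reading errors.
####-##-####	0,1,2,3,4,5,6,7,8,18,19,20
#-########-#	2,12,15,16,18,19,20,21
####-#-------#-####	0,1,11,14
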