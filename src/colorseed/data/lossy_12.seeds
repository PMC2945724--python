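; 3-Lossy-12: three weight-12 seeds applied at all positions.
####-####-####	*
####-###--#----####	*
####----##--##-####	*
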