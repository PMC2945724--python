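; PerM F3 and S20 periodic seeds taken together, all positions.
###-#--#---###-#--#---##	*
####--#----####--#----##	*
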