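sample_id	stratum	aao_years
NMC1	PROTECTED
NMC2	PROTECTED
L2PD1	CASE_MUTANT	55.0
L2PD2	CASE_MUTANT	62.5
IDPD1	CASE_IDIOPATHIC	60.0
CTRL1	CONTROL
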