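# candidate genes linked to LRRK2 function
GAK
RAB29
VPS35
DNAJC6
SNCA
LRRK2
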