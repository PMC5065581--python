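gene	disorder
HCN1	Early infantile epileptic encephalopathy 24
SCN1A	Dravet syndrome
TCF4	Pitt-Hopkins syndrome
GRIN2B	Autosomal dominant mental retardation 6; early infantile epileptic encephalopathy 27
SLC6A1	Myoclonic-atonic epilepsy and schizophrenia
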