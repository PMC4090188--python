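marker	chr	pos	nearest_gene	distance	P	var_pct
H3GA0020739	7	34556148	IP6K3	within	2.01E-08	46.60
H3GA0020765	7	34755602	LOC102164675	41168	1.50E-08	46.81
MARC0058766	7	34803564	GRM4	34993	1.20E-08	46.98
MARC0033464	7	35177641	C7H6orf106	within	1.71E-08	46.62
MARC0039836	7	35935629	LOC102166984	within	2.53E-08	46.51
H3GA0020849	7	36004578	LOC100738130	within	2.66E-08	46.25
ASGA0032595	7	36497507	LOC100521322	4106	2.80E-08	47.21
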