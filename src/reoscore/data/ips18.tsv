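gene_a	gene_b
CXCL11	ETNK2
CXCL11	FZD9
CXCL11	CDH5
CXCL11	ZSCAN2
CXCL11	PAMR1
CXCL11	LRP12
CXCL11	NEURL2
CXCL11	DAAM2
CXCL11	CDK5R1
CXCL11	TSPYL5
CXCL11	DRD4
CXCL11	LOC101928837
CXCL10	SP2
CXCL10	PLOD1
TNFSF4	CSPG4
TNFRSF10A	CDHR2
GZMB	ACKR3
NEDD4	CAMSAP3
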