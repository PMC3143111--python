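# phase	gene	class
G1	SWI4	tf
G1	MBP1	tf
G1	STB1	tf
G1	SWI6	tf
G1	ACE2	tf
G1	SKN7	tf
G1	CLN3	cdk_cyclin_cdc
G1	FUS3	cdk_cyclin_cdc
G1	FAR1	cdk_cyclin_cdc
G1	CDC36	cdk_cyclin_cdc
G1	CDC39	cdk_cyclin_cdc
G1	CLN2	cdk_cyclin_cdc
G1	CDC37	cdk_cyclin_cdc
G1	CDC28	cdk_cyclin_cdc
G1	CLN1	cdk_cyclin_cdc
S	SWI4	tf
S	MBP1	tf
S	NDD1	tf
S	SWI6	tf
S	SKN7	tf
S	CDC24	cdk_cyclin_cdc
S	CDC7	cdk_cyclin_cdc
S	CDC8	cdk_cyclin_cdc
S	CDC21	cdk_cyclin_cdc
G2	FKH1	tf
G2	FKH2	tf
G2	NDD1	tf
G2	MCM1	tf
G2	CDC11	cdk_cyclin_cdc
G2	CLB2	cdk_cyclin_cdc
G2	CDC15	cdk_cyclin_cdc
G2	CLB4	cdk_cyclin_cdc
G2	CDC28	cdk_cyclin_cdc
G2	CDC3	cdk_cyclin_cdc
G2	CDC5	cdk_cyclin_cdc
G2	CDC14	cdk_cyclin_cdc
G2	CLB1	cdk_cyclin_cdc
G2	CLB3	cdk_cyclin_cdc
M	MCM1	tf
M	SWI5	tf
M	ACE2	tf
M	CDC28	cdk_cyclin_cdc
M	CLB1	cdk_cyclin_cdc
M	CLB2	cdk_cyclin_cdc
M	CLB3	cdk_cyclin_cdc
M	CLB4	cdk_cyclin_cdc
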