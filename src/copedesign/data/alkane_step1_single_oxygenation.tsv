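enzyme	n-tetradecane	norphytane	cyclopentane
6CXH	-91.013	-124.464	-28.367
4USQ	-69.372	-100.321	-25.052
6HNS	-86.015	-90.152	-30.944
3E5K	-108.902	-131.824	-28.575
1SMJ	-66.647	-75.650	-44.472
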