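enzyme	dodecan-1-ol	2,6,10-trimethylpentadecane-1,14-diol	cyclopentanone
3E5K	-69.416	-154.453	-26.549
7BU3	-75.925	-80.793	-23.091
1Q1N	-73.881	-76.893	-26.337
6K10	-80.342	-130.382	-27.720
4CAZ	-88.832	-121.662	-35.881
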