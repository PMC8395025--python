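# Documentation-only fixture: bioconcentration (logBCF) and octanol-air
# partition (logKOA) estimates for the four parent pollutants and the final
# degradation products of the retained pathways.  Not used by any computation.
compound	role	logBCF	logKOA
n-tetradecane	pollutant	3.430	4.625
norphytane	pollutant	2.362	5.937
cyclopentane	pollutant	1.646	2.207
benzene	pollutant	1.072	2.780
adipic acid	product	0.500	9.795
2-methyl-1,3-propanediol	product	0.500	8.825
3-hydroxypropionic acid	product	0.500	8.074
succinic acid	product	0.500	10.246
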