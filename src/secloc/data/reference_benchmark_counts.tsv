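group	rule	tp	fp	tn	fn	sn	sp	mcc
mitochondrial	targetp	930	972	16032	940	49.7	94.3	0.44
mitochondrial	wolfpsort	920	482	16522	950	49.2	97.2	0.53
mitochondrial	targetp_and_wolfpsort	794	262	16742	1076	42.5	98.5	0.53
mitochondrial	targetp_or_wolfpsort	1056	1202	15802	814	56.5	92.9	0.45
secreted	secreted_4of4	5024	276	12874	700	87.8	97.9	0.88
secreted	s_hls	5350	522	12628	374	93.5	96.0	0.89
secreted	s_hls_ls	5413	794	12356	311	94.6	94.0	0.87
secreted	s_hls_ls_wls	5440	1462	11688	284	95.0	88.9	0.80
locations	cytoplasm	1095	1124	15779	876	55.6	93.4	0.46
locations	cytoskeleton	218	63	18020	573	27.6	99.7	0.45
locations	er	257	187	17906	524	32.9	99.0	0.42
locations	golgi	12	21	18584	257	4.5	99.9	0.12
locations	lysosome	1	8	18675	190	0.5	100.0	0.02
locations	nucleus	2979	893	14190	812	78.6	94.1	0.72
locations	peroxisome	4	101	18653	116	3.3	99.5	0.03
locations	plasma_membrane	2767	647	14880	580	82.7	95.8	0.78
locations	vacuole	0	0	18855	19	0.0	100.0	-
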