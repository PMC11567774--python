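# adjusted values computed with R sva::ComBat 3.50 (par.prior=TRUE) on the fixture generated by tests/test_harmonize.py::_reference_fixture
2.5949961	2.0150532	2.157285	3.3990343	2.066372	3.2603241
1.9596786	2.1867418	2.9048822	-0.36362637	1.1238936	1.1890538
0.79276289	0.82400024	3.5736977	0.60387624	3.0878738	-0.46408198
1.4999373	2.0643691	2.7689088	3.129873	2.9314127	1.5676725
0.33373009	2.3356586	1.0407201	-0.19406306	-0.40469036	0.20640225
2.9496663	1.487417	2.2473728	1.3229244	1.8608194	3.2989104
1.6104866	2.5265366	0.7398894	1.4359874	1.1201567	0.26307572
2.7390299	0.51054128	1.2000979	2.728538	2.2545885	3.2268734
1.0209757	0.40484459	1.2124138	-0.84130871	-0.88354321	-0.41206519
-0.26443433	1.7369489	-0.19852383	1.2998753	3.4854974	1.3586132
2.2128406	0.80351187	1.6981883	0.68571838	1.2865643	2.1330319
-0.168881	2.4003778	1.9564867	1.2602241	0.30597797	1.498848
0.82985655	1.9963423	1.5913093	3.0458372	1.3446554	-0.03488321
1.7481901	2.058709	3.4464276	2.5034977	2.1336749	3.0415163
0.2452751	1.2405536	0.74157633	1.2877311	0.24568281	1.9555714
0.76078066	-0.53523289	0.080332541	1.4087981	2.1301283	3.147454
4.3852761	2.2067388	0.20023198	-0.56736901	1.8067158	0.13432143
0.40212711	0.5742694	1.2212708	1.9533897	1.2642434	0.47375117
0.77036625	-0.013073335	1.4364648	1.9935494	3.9230567	1.6985092
2.7186595	1.5179623	0.44081371	0.93541222	1.1015548	3.8735796
0.6414309	2.8209061	0.57144039	3.1788927	2.4364132	1.7186697
1.0667374	0.12803535	1.6486321	0.25574512	-0.7184514	-0.70069735
1.9242169	4.0190079	2.2176478	1.5394575	2.197617	3.5146313
2.2086717	1.2939614	3.5189812	2.6390357	4.2261519	2.3302402
0.10059909	-0.17126619	4.0824663	4.3336413	1.6700627	1.4277038
3.29575	-0.60411974	-0.29412797	2.0325406	0.61583082	1.3316115
0.99872761	1.6378803	3.1330563	1.1793486	2.0509395	-1.6470188
0.77257891	-0.55043748	-1.1031481	-0.75276847	0.13275665	1.9961698
-0.60947387	0.89810825	0.20245594	0.59678714	2.5257223	2.0381244
3.568635	1.360481	0.73667329	1.4351218	2.1397046	2.0988251
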