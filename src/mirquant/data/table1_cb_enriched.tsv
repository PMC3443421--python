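name	locations	pb_rpkm	cb_rpkm	fold	pb_rank	cb_rank
hsa-mir-136	chr14:101351053-101351075	0	495.64316	9.90E+307	770	95
hsa-mir-376c	chr14:101506069-101506089	1.2448007	1174.4226	943.4623551	483	68
hsa-mir-494	chr14:101496018-101496039	3.3418648	3083.2217	922.6051575	382	33
hsa-mir-376a*	chr14:101507125-101507146	3.1190746	2104.9521	674.8643011	389	47
hsa-mir-376a	chr14:101506455-101506475,chr14:101507162-101507182	0.7002004	359.68243	513.6849822	542	106
hsa-mir-377	chr14:101528431-101528452	0.89116406	305.87003	343.2252755	514	116
hsa-mir-410	chr14:101532298-101532318	1.4004008	399.5301	285.2969664	468	101
hsa-mir-381	chr14:101512305-101512326	6.6837296	1888.779	282.5935687	316	54
hsa-mir-411	chr14:101489677-101489697	5.134803	1427.5367	278.0119705	341	63
hsa-mir-889	chr14:101514286-101514306	1.4004008	309.84427	221.2539939	468	113
hsa-mir-379	chr14:101488408-101488428	27.541208	4422.998	160.5956427	221	27
hsa-mir-369-3p	chr14:101531978-101531998	5.6016035	868.6908	155.0789519	334	81
hsa-mir-134	chr14:101521031-101521052	10.9167595	910.0818	83.36556283	281	77
hsa-mir-29b	chr7:130562226-130562248,chr1:207975795-207975817	84.74453	6061.3887	71.52542707	162	20
hsa-mir-222*	chrX:45606479-45606500	25.843756	1562.2592	60.45016057	223	61
hsa-mir-31	chr9:21512157-21512177	347.53278	15717.314	45.22541442	93	7
hsa-mir-127-3p	chr14:101349372-101349393	64.60941	2614.9524	40.47324376	174	39
hsa-mir-654-3p	chr14:101506606-101506627	16.932117	517.527	30.5648136	255	91
hsa-mir-146a	chr5:159912379-159912400	1061.7109	7229.664	6.809446903	65	15
hsa-mir-216a	chr2:56216155-56216176	462.73697	3054.6147	6.601190089	84	34
hsa-mir-18b	chrX:133304114-133304136	95.57735	621.04553	6.497831652	152	90
hsa-mir-24-2*	chr19:13947140-13947161	126.99086	810.7064	6.383974406	144	84
hsa-mir-503	chrX:133680401-133680423	83.323845	498.72934	5.985433581	163	94
hsa-mir-18a	chr13:92003010-92003032	116.24848	684.41486	5.887516637	147	87
hsa-mir-4792	chr3:24562903-24562920	56.91072	308.37952	5.418654341	181	114
hsa-mir-19a	chr13:92003193-92003215	168.31697	886.21814	5.265174034	130	80
hsa-mir-19b	chrX:133303713-133303735,chr13:92003499-92003521	351.0184	1759.4749	5.01248624	92	58
hsa-mir-185	chr22:20020676-20020697	130.77832	639.70306	4.891506941	142	89
hsa-mir-424	chrX:133680710-133680731	326.61172	1557.3126	4.768085481	97	62
hsa-mir-24	chr9:97848346-97848367,chr19:13947103-13947124	39987.26	172634.36	4.317234039	5	2
hsa-mir-196a	chr17:46709894-46709915,chr12:54385546-54385567	93.497955	398.9361	4.266789578	156	102
hsa-mir-130a	chr11:57408725-57408746	319.70517	1143.3563	3.576283424	98	70
hsa-mir-345	chr14:100774213-100774234	137.23924	455.79385	3.321162737	138	98
hsa-mir-32	chr9:111808552-111808573	94.68617	312.1079	3.296235343	153	112
hsa-mir-339-3p	chr7:1062591-1062613	116.35501	376.72174	3.237692472	146	105
hsa-mir-186	chr1:71533364-71533385	1265.8989	3930.9248	3.105243871	57	30
hsa-mir-20b	chrX:133303880-133303902	393.07117	1119.9288	2.849175634	90	72
hsa-mir-542-3p	chrX:133675394-133675415	302.77307	758.6524	2.505679914	100	85
hsa-mir-877	chr6:30552109-30552128	134.05331	333.61777	2.488694759	140	110
hsa-mir-106b	chr7:99691666-99691686	1116.7422	2731.2852	2.445761609	62	36
hsa-mir-452	chrX:151128150-151128171	466.9701	1105.1763	2.366696069	82	73
hsa-mir-22	chr17:1617208-1617229	1037.9835	2326.5046	2.24136954	66	42
hsa-mir-374a*	chrX:73507130-73507151	1247.1844	2619.4692	2.100306258	60	38
hsa-mir-29c	chr1:207975210-207975231	1326.5715	2675.448	2.01681402	53	37
hsa-mir-29a	chr7:130561507-130561528	1443.6847	2802.1428	1.940965919	50	35
hsa-mir-30e	chr1:41220043-41220064	5007.227	9227.503	1.842836963	26	10
hsa-mir-99a	chr21:17911421-17911442	2773.0786	5025.056	1.812085673	41	24
hsa-mir-20a	chr13:92003326-92003348	1287.8253	2302.079	1.787570876	54	43
hsa-mir-15a	chr13:50623303-50623324	483.79068	822.4292	1.699969086	81	83
hsa-mir-100	chr11:122022983-122023004	4361.801	7380.455	1.692065961	28	14
hsa-mir-106a	chrX:133304274-133304296	1250.3193	2036.8033	1.629026521	59	50
hsa-mir-17	chr13:92002872-92002894	1266.1599	2058.4065	1.625708175	56	48
hsa-mir-27a	chr19:13947261-13947281	5321.171	8077.8022	1.51804973	25	12
hsa-mir-140-5p	chr16:69967006-69967027	334.1866	501.82477	1.501630436	96	93
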