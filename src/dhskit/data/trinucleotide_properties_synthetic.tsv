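trinucleotide	bendability_dnase	bendability_consensus	gc_content	nucleosome_positioning	consensus_roll	consensus_rigid	dnase_i	dnase_i_rigid	mw_daltons	mw_kg	nucleosome	nucleosome_rigid
AAA	-0.0022	0.1615	0	0.3965	1.5915	0.7868	-0.0259	3.971	939.63	1560.2932	-0.7847	4.8399
AAC	0.019	-0.002	1	0.1222	5.692	3.5879	0.0584	2.8568	915.6	1520.3904	0.5516	5.2415
AAG	0.0832	0.0207	1	-0.0043	3.7239	5.8011	0.0059	2.8829	955.63	1586.8618	-0.9382	3.2094
AAT	0.0589	-0.0646	0	1.1831	0.3734	5.9903	-0.0542	3.9289	930.62	1545.3317	0.1233	6.3832
ACA	0.1146	0.1362	1	0.61	1.4743	5.0639	0.0689	4.0977	915.6	1520.3904	0.2335	3.9231
ACC	0.277	0.2497	2	0.8333	1.1507	4.4746	0.0711	1.2084	891.57	1480.4876	0.6672	4.1047
ACG	0.1723	0.1317	2	-0.7573	2.7314	8.2254	0.0821	3.6785	931.6	1546.9591	-0.3981	2.3207
ACT	0.1054	0.0611	1	-1.1833	2.131	0.9211	0.0296	4.1199	906.59	1505.429	0.627	5.5444
AGA	0.0149	0.0698	1	-0.0845	3.1943	6.2972	0.1104	1.9136	955.63	1586.8618	0.5705	5.1838
AGC	0.1756	0.1511	2	-0.2301	3.5445	2.4785	0.1136	3.026	931.6	1546.9591	-0.8337	3.6726
AGG	0.1525	0.1768	2	-0.002	2.4098	4.1878	0.0878	2.0298	971.63	1613.4305	0.475	3.5678
AGT	0.0487	0.1043	1	-0.7369	1.7974	3.6493	0.0251	4.4434	946.62	1571.9004	-0.6516	3.5148
ATA	-0.0032	0.0207	0	-0.6889	4.1588	6.7273	0.036	1.8739	930.62	1545.3317	-0.3437	3.7599
ATC	0.0699	0.0406	1	-0.1272	0.5207	6.3778	0.0761	2.4453	906.59	1505.429	-0.0506	3.7874
ATG	0.067	-0.0092	1	-0.6413	3.4291	6.5884	0.0272	3.4859	946.62	1571.9004	0.9566	5.5982
ATT	0.0163	0.0891	0	-0.1659	0.2301	4.1127	0.0291	3.7185	921.61	1530.3703	0.7958	2.2966
CAA	0.1695	-0.0477	1	-0.3675	1.8833	4.4528	0.0139	2.1636	915.6	1520.3904	-0.05	3.2126
CAC	0.1255	0.1561	2	-0.2559	0.8633	5.4867	0.1532	3.2271	891.57	1480.4876	0.5115	2.0824
CAG	0.0801	0.1376	2	-0.0173	1.917	3.7214	0.0462	2.842	931.6	1546.9591	0.5511	5.2935
CAT	0.0546	0.109	1	-1.0758	4.8807	5.0655	0.0471	2.5378	906.59	1505.429	-0.7808	3.9468
CCA	0.144	0.1923	2	0.6533	0.998	10.7457	0.102	3.0627	891.57	1480.4876	-0.8916	3.5663
CCC	0.4356	0.2268	3	0.1031	2.2969	8.9227	0.1438	3.0336	867.54	1440.5849	0.5328	2.571
CCG	0.3088	0.1885	3	0.1997	4.7596	5.8083	0.1927	2.158	907.57	1507.0563	-0.2921	3.6511
CCT	0.1743	0.2067	2	0.5342	0.6693	4.3867	0.1195	2.0077	882.56	1465.5262	0.4705	2.8803
CGA	0.2153	0.1578	2	0.0772	4.4674	4.8124	0.0811	2.9561	931.6	1546.9591	-0.4775	3.0056
CGC	0.3323	0.2842	3	0.0944	2.261	4.0383	0.191	2.9268	907.57	1507.0563	-1.2575	2.4441
CGG	0.3162	0.2449	3	0.4593	5.1454	3.6287	0.2045	3.2487	947.6	1573.5277	0.4781	5.8142
CGT	0.2245	0.1179	2	-0.1706	3.9862	7.6257	0.0308	3.786	922.59	1531.9976	-0.3765	3.4848
CTA	0.1482	0.0848	1	-0.9532	-0.3425	6.1222	0.0579	4.5531	906.59	1505.429	-0.5728	0.8182
CTC	0.1529	0.1175	2	-0.7265	-1.7639	5.9861	0.0855	3.7346	882.56	1465.5262	0.5911	3.9961
CTG	0.0903	0.2087	2	0.1519	0.3673	9.2416	0.1387	2.9642	922.59	1531.9976	1.0889	3.1395
CTT	0.0647	-0.0058	1	-0.5934	1.4287	4.6569	0.021	3.4933	897.58	1490.4675	-0.4492	3.0968
GAA	0.1486	0.0818	1	0.1668	0.7718	6.1146	0.0993	3.382	955.63	1586.8618	0.1577	2.5493
GAC	0.2448	0.1855	2	-0.2104	1.7711	6.9923	0.0872	3.4463	931.6	1546.9591	-0.5205	4.1839
GAG	0.2639	0.1101	2	0.0611	2.6356	4.4135	0.0972	4.0106	971.63	1613.4305	0.5726	2.971
GAT	0.2673	0.0514	1	0.3248	1.7122	7.6178	0.0683	3.9331	946.62	1571.9004	-0.1897	4.9369
GCA	0.164	0.214	2	0.4267	3.3134	2.006	0.0769	5.1495	931.6	1546.9591	0.0226	5.6997
GCC	0.3807	0.2575	3	-0.6503	1.9756	4.2295	0.1226	4.5611	907.57	1507.0563	0.1714	3.5867
GCG	0.3299	0.2585	3	-0.5037	0.8128	2.8208	0.1905	3.0094	947.6	1573.5277	-0.8643	5.3596
GCT	0.225	0.2655	2	0.0495	2.9576	-0.1031	0.1453	3.0852	922.59	1531.9976	1.2757	4.2375
GGA	0.2007	0.2061	2	-1.1253	2.59	5.6769	0.122	1.9436	971.63	1613.4305	-0.5646	5.3518
GGC	0.2642	0.2178	3	-0.9582	2.0111	6.7785	0.1806	4.4913	947.6	1573.5277	0.0894	4.3873
GGG	0.329	0.1613	3	0.0354	1.1841	6.5824	0.0873	2.7056	987.63	1639.9991	-0.6993	4.0601
GGT	0.178	0.1346	2	0.1313	1.988	3.3098	0.0847	2.9781	962.62	1598.469	0.203	4.9213
GTA	0.0796	0.0362	1	0.0822	3.1951	4.6824	0.0738	3.2557	946.62	1571.9004	0.1822	1.3503
GTC	0.1848	0.1853	2	0.3722	0.0884	5.4396	0.0962	4.0194	922.59	1531.9976	0.1559	5.862
GTG	0.1437	0.1204	2	0.1669	0.6598	2.6968	0.1071	3.6502	962.62	1598.469	-0.886	4.3968
GTT	0.1321	0.0566	1	-0.0345	1.3286	4.3565	0.0226	1.0005	937.61	1556.9389	-0.0828	0.4978
TAA	-0.0236	0.0134	0	0.4173	1.24	6.637	-0.0099	2.3875	930.62	1545.3317	0.4172	4.1208
TAC	0.1095	0.0732	1	0.4793	2.1488	0.5998	0.0531	3.0965	906.59	1505.429	-0.0692	4.4252
TAG	0.0822	-0.0561	1	0.036	3.4401	2.0534	0.0796	4.0528	946.62	1571.9004	-0.2818	4.5164
TAT	-0.0715	0.0256	0	-0.0492	4.0016	8.1807	-0.014	1.9893	921.61	1530.3703	0.4282	5.4859
TCA	0.1918	0.1318	1	0.4261	0.0913	3.7202	0.0241	1.9615	906.59	1505.429	-0.0773	2.562
TCC	0.1319	0.1669	2	0.263	4.265	5.0925	0.0902	2.7992	882.56	1465.5262	0.3753	4.6012
TCG	0.0648	0.11	2	-0.2778	3.0925	3.4248	0.1569	3.8089	922.59	1531.9976	0.8644	6.694
TCT	0.1099	0.1533	1	0.2032	-0.1553	5.2216	0.0158	2.0775	897.58	1490.4675	0.168	3.9824
TGA	0.081	0.094	1	0.4215	1.0548	4.2008	0.0294	2.8176	946.62	1571.9004	-0.2805	3.2524
TGC	0.2064	0.1856	2	-0.1015	0.1532	4.9855	0.0471	2.3347	922.59	1531.9976	0.279	3.462
TGG	0.1766	0.2422	2	0.5729	2.7028	3.2584	0.1182	2.8952	962.62	1598.469	0.1643	3.6815
TGT	0.1554	0.0522	1	0.1354	1.8383	6.0186	0.0582	4.5853	937.61	1556.9389	-1.0196	3.4901
TTA	-0.0245	0.0061	0	-0.1667	5.385	6.4759	-0.012	2.0311	921.61	1530.3703	-0.1732	3.0828
TTC	0.0618	0.124	1	0.0348	1.6881	3.8004	-0.0039	3.6701	897.58	1490.4675	0.1034	3.9649
TTG	0.0196	0.0485	1	-0.8535	0.8924	1.1084	0.0685	2.7316	937.61	1556.9389	-0.6095	5.7262
TTT	-0.0683	-0.0288	0	0.0896	2.1453	4.7827	0.0599	2.8932	912.6	1515.4088	1.041	5.5046
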