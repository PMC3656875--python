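chrom	size_mbp	genes	gbs_snps	beadchip_snps
1	158.34	1065	2322	3429
2	137.06	1038	2198	2828
3	121.43	1494	2419	2548
4	120.83	886	2110	2569
5	121.19	1525	2547	2270
6	119.46	757	2006	2574
7	112.64	1592	1966	2351
8	113.38	904	1869	2428
9	105.71	704	1716	2094
10	104.31	1219	1969	2205
11	107.31	1084	2484	2294
12	91.16	490	1788	1772
13	82.24	918	1877	1849
14	84.65	602	1432	1830
15	85.30	1357	1457	1761
16	81.72	771	1868	1725
17	75.16	725	1408	1599
18	66.00	1433	1596	1375
19	64.06	1366	1869	1419
20	72.04	395	1566	1566
21	71.60	703	1961	1482
22	61.44	627	1523	1323
23	52.53	849	1509	1092
24	62.71	374	1453	1311
25	42.90	773	1614	1003
26	51.68	469	1188	1116
27	45.41	299	977	980
28	46.31	364	1149	979
29	51.51	806	1573	1085
X	148.82	1401	1143	1169
unmapped			191	
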