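chromosome	gene_id	ensembl_gene	location	transcript_id	cds_bp	exons	protein_aa	mw_kda	pi	domain_aa
1A	TdGLYI-1A-1	TRITD1Av1G050960	117714194-117715361	TdGLYI-1A-1.1	294	3	97	10.8	6.87	76
1A	TdGLYI-1A-1	TRITD1Av1G050960	117714194-117715361	TdGLYI-1A-1.2	642	3	213	23.0	5.55	119
1A	TdGLYI-1A-2	TRITD1Av1G051320	118907676-118908570	TdGLYI-1A-2.1	615	3	204	22.4	6.21	119
1A	TdGLYI-1A-3	TRITD1Av1G068400	176831236-176834697	TdGLYI-1A-3.1	723	7	240	26.9	4.61	78
1B	TdGLYI-1B-1	TRITD1Bv1G059850	164193298-164196003	TdGLYI-1B-1.1	300	2	99	10.9	7.28	76
1B	TdGLYI-1B-1	TRITD1Bv1G059850	164193298-164196003	TdGLYI-1B-1.2	651	3	216	23.3	5.24	119
1B	TdGLYI-1B-2	TRITD1Bv1G060140	164863825-164864805	TdGLYI-1B-2.1	615	3	204	22.4	6.21	119
1B	TdGLYI-1B-3	TRITD1Bv1G064590	179215549-179218166	TdGLYI-1B-3.1	549	4	182	20.0	8.85	122
1B	TdGLYI-1B-4	TRITD1Bv1G076140	219592925-219597535	TdGLYI-1B-4.1	981	9	326	35.6	8.4	121
1B	TdGLYI-1B-4	TRITD1Bv1G076140	219592925-219597535	TdGLYI-1B-4.2	1110	11	369	40.6	9.06	148
1B	TdGLYI-1B-4	TRITD1Bv1G076140	219592925-219597535	TdGLYI-1B-4.3	1029	10	342	37.5	8.88	121
1B	TdGLYI-1B-4	TRITD1Bv1G076140	219592925-219597535	TdGLYI-1B-4.4	1032	10	343	37.7	8.88	121
1B	TdGLYI-1B-4	TRITD1Bv1G076140	219592925-219597535	TdGLYI-1B-4.5	1053	10	350	38.6	6.87	121
1B	TdGLYI-1B-4	TRITD1Bv1G076140	219592925-219597535	TdGLYI-1B-4.6	1005	9	334	36.7	6.17	121
1B	TdGLYI-1B-4	TRITD1Bv1G076140	219592925-219597535	TdGLYI-1B-4.7	804	6	267	29.2	7.61	121
2A	TdGLYI-2A-1	TRITD2Av1G015960	30445352-30449760	TdGLYI-2A-1.1	717	8	238	26.0	8.88	143
2A	TdGLYI-2A-1	TRITD2Av1G015960	30445352-30449760	TdGLYI-2A-1.2	711	8	236	26.0	8.88	143
2A	TdGLYI-2A-1	TRITD2Av1G015960	30445352-30449760	TdGLYI-2A-1.3	717	8	238	26.0	8.88	143
2A	TdGLYI-2A-2	TRITD2Av1G037690	79355005-79355968	TdGLYI-2A-2.1	705	3	234	25.9	6.83	122
2B	TdGLYI-2B-1	TRITD2Bv1G021700	46175435-46180632	TdGLYI-2B-1.1	729	8	242	26.5	9.64	143
2B	TdGLYI-2B-1	TRITD2Bv1G021700	46175435-46180632	TdGLYI-2B-1.2	735	8	244	26.8	9.64	143
2B	TdGLYI-2B-2	TRITD2Bv1G050840	130332981-130333966	TdGLYI-2B-2.1	690	3	229	25.6	6.69	122
2B	TdGLYI-2B-3	TRITD2Bv1G190210	564302032-564302867	TdGLYI-2B-3.1	507	3	168	18.7	6.21	121
3A	TdGLYI-3A-1	TRITD3Av1G045760	101391289-101393613	TdGLYI-3A-1.1	738	3	245	26.1	5.76	121
3A	TdGLYI-3A-1	TRITD3Av1G045760	101391289-101393613	TdGLYI-3A-1.2	684	4	227	24.3	6.06	121
3B	TdGLYI-3B-1	TRITD3Bv1G053730	146528005-146530829	TdGLYI-3B-1.1	732	3	243	25.9	6.28	121
3B	TdGLYI-3B-1	TRITD3Bv1G053730	146528005-146530829	TdGLYI-3B-1.2	477	2	158	17.3	10.8	85
3B	TdGLYI-3B-2	TRITD3Bv1G262600	788647776-788648159	TdGLYI-3B-2.1	384	1	127	14.1	4.83	121
4A	TdGLYI-4A-1	TRITD4Av1G045690	109207764-109208269	TdGLYI-4A-1.1	417	2	138	15.4	6.71	123
4A	TdGLYI-4A-2	TRITD4Av1G201720	588467710-588469500	TdGLYI-4A-2.1	390	1	129	14.0	5.6	123
4A	TdGLYI-4A-2	TRITD4Av1G201720	588467710-588469500	TdGLYI-4A-2.2	426	2	141	15.1	5.6	128
4B	TdGLYI-4B-1	TRITD4Bv1G004210	10899645-10902500	TdGLYI-4B-1.1	420	2	139	15.0	5.6	126
4B	TdGLYI-4B-1	TRITD4Bv1G004210	10899645-10902500	TdGLYI-4B-1.2	417	2	138	14.9	5.6	121
4B	TdGLYI-4B-2	TRITD4Bv1G120890	424968636-424969143	TdGLYI-4B-2.1	417	2	138	15.3	5.7	122
4B	TdGLYI-4B-2	TRITD4Bv1G120890	424968636-424969143	TdGLYI-4B-2.2	321	3	106	11.7	10.9	Absent
5A	TdGLYI-5A-1	TRITD5Av1G224460	594195163-594197060	TdGLYI-5A-1.1	1002	9	333	36.8	9.5	121
5A	TdGLYI-5A-2	TRITD5Av1G224480	594236444-594238326	TdGLYI-5A-2.1	1128	9	375	40.7	8.2	121
5A	TdGLYI-5A-2	TRITD5Av1G224480	594236444-594238326	TdGLYI-5A-2.2	693	7	230	25.4	4.7	97
5A	TdGLYI-5A-2	TRITD5Av1G224480	594236444-594238326	TdGLYI-5A-2.3	1047	9	348	37.8	7.1	121
5A	TdGLYI-5A-2	TRITD5Av1G224480	594236444-594238326	TdGLYI-5A-2.4	789	7	262	28.5	9.2	121
5B	TdGLYI-5B-1	TRITD5Bv1G224000	634683230-634685025	TdGLYI-5B-1.1	789	7	262	28.5	9.4	121
5B	TdGLYI-5B-1	TRITD5Bv1G224000	634683230-634685025	TdGLYI-5B-1.2	1047	9	348	37.8	6.5	121
5B	TdGLYI-5B-1	TRITD5Bv1G224000	634683230-634685025	TdGLYI-5B-1.3	1059	8	352	38.8	6.1	121
6A	TdGLYI-6A-1	TRITD6Av1G049270	114843229-114860565	TdGLYI-6A-1.1	1302	3	433	46.3	5.4	157
6A	TdGLYI-6A-1	TRITD6Av1G049270	114843229-114860565	TdGLYI-6A-1.2	1302	2	433	46.4	5.6	157
6A	TdGLYI-6A-1	TRITD6Av1G049270	114843229-114860565	TdGLYI-6A-1.3	1242	3	413	44.2	5.4	157
6A	TdGLYI-6A-1	TRITD6Av1G049270	114843229-114860565	TdGLYI-6A-1.4	945	3	314	33.8	4.3	157
6A	TdGLYI-6A-2	TRITD6Av1G135140	393587685-393590576	TdGLYI-6A-2.1	978	9	325	36.3	7.2	122
6A	TdGLYI-6A-2	TRITD6Av1G135140	393587685-393590576	TdGLYI-6A-2.2	537	5	178	19.9	5.4	122
6B	TdGLYI-6B-1	TRITD6Bv1G061930	175495718-175504903	TdGLYI-6B-1.1	1311	4	436	46.7	5.4	157
6B	TdGLYI-6B-1	TRITD6Bv1G061930	175495718-175504903	TdGLYI-6B-1.2	1251	4	416	44.6	5.4	157
6B	TdGLYI-6B-1	TRITD6Bv1G061930	175495718-175504903	TdGLYI-6B-1.3	1257	3	418	44.9	6.0	157
6B	TdGLYI-6B-1	TRITD6Bv1G061930	175495718-175504903	TdGLYI-6B-1.4	1311	2	436	46.7	5.4	157
7A	TdGLYI-7A-1	TRITD7Av1G199820	539974526-539977164	TdGLYI-7A-1.1	537	5	178	19.9	5.1	122
7A	TdGLYI-7A-1	TRITD7Av1G199820	539974526-539977164	TdGLYI-7A-1.2	570	5	189	21.1	4.6	122
7A	TdGLYI-7A-1	TRITD7Av1G199820	539974526-539977164	TdGLYI-7A-1.3	879	8	292	32.6	5.1	122
7A	TdGLYI-7A-1	TRITD7Av1G199820	539974526-539977164	TdGLYI-7A-1.4	876	8	291	32.6	5.3	122
7B	TdGLYI-7B-1	TRITD7Bv1G146550	462865131-462871241	TdGLYI-7B-1.1	1110	9	369	41.2	6.7	122
7B	TdGLYI-7B-1	TRITD7Bv1G146550	462865131-462871241	TdGLYI-7B-1.2	687	7	228	25.6	4.5	122
7B	TdGLYI-7B-1	TRITD7Bv1G146550	462865131-462871241	TdGLYI-7B-1.3	570	5	189	21.1	4.6	122
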