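# Coarse SYNTHETIC arm-level band track for H. sapiens GRCh37: one gpos50 p-arm band,
# one acen centromere band (approximate centromere +/- 3 Mb), one gneg q-arm band per
# chromosome. Not the published Giemsa band table; a stand-in outer reference ring.
# columns: chrom	start	end	band	stain
1	1	121999999	1p	gpos50
1	122000000	128000000	1cen	acen
1	128000001	249250621	1q	gneg
2	1	90299999	2p	gpos50
2	90300000	96300000	2cen	acen
2	96300001	243199373	2q	gneg
3	1	87999999	3p	gpos50
3	88000000	94000000	3cen	acen
3	94000001	198022430	3q	gneg
4	1	47399999	4p	gpos50
4	47400000	53400000	4cen	acen
4	53400001	191154276	4q	gneg
5	1	45399999	5p	gpos50
5	45400000	51400000	5cen	acen
5	51400001	180915260	5q	gneg
6	1	57999999	6p	gpos50
6	58000000	64000000	6cen	acen
6	64000001	171115067	6q	gneg
7	1	56899999	7p	gpos50
7	56900000	62900000	7cen	acen
7	62900001	159138663	7q	gneg
8	1	42599999	8p	gpos50
8	42600000	48600000	8cen	acen
8	48600001	146364022	8q	gneg
9	1	45999999	9p	gpos50
9	46000000	52000000	9cen	acen
9	52000001	141213431	9q	gneg
10	1	37199999	10p	gpos50
10	37200000	43200000	10cen	acen
10	43200001	135534747	10q	gneg
11	1	50699999	11p	gpos50
11	50700000	56700000	11cen	acen
11	56700001	135006516	11q	gneg
12	1	32799999	12p	gpos50
12	32800000	38800000	12cen	acen
12	38800001	133851895	12q	gneg
13	1	14899999	13p	gpos50
13	14900000	20900000	13cen	acen
13	20900001	115169878	13q	gneg
14	1	14599999	14p	gpos50
14	14600000	20600000	14cen	acen
14	20600001	107349540	14q	gneg
15	1	15999999	15p	gpos50
15	16000000	22000000	15cen	acen
15	22000001	102531392	15q	gneg
16	1	33599999	16p	gpos50
16	33600000	39600000	16cen	acen
16	39600001	90354753	16q	gneg
17	1	20999999	17p	gpos50
17	21000000	27000000	17cen	acen
17	27000001	81195210	17q	gneg
18	1	14199999	18p	gpos50
18	14200000	20200000	18cen	acen
18	20200001	78077248	18q	gneg
19	1	23499999	19p	gpos50
19	23500000	29500000	19cen	acen
19	29500001	59128983	19q	gneg
20	1	24499999	20p	gpos50
20	24500000	30500000	20cen	acen
20	30500001	63025520	20q	gneg
21	1	10199999	21p	gpos50
21	10200000	16200000	21cen	acen
21	16200001	48129895	21q	gneg
22	1	11699999	22p	gpos50
22	11700000	17700000	22cen	acen
22	17700001	51304566	22q	gneg
X	1	57599999	Xp	gpos50
X	57600000	63600000	Xcen	acen
X	63600001	155270560	Xq	gneg
Y	1	9499999	Yp	gpos50
Y	9500000	15500000	Ycen	acen
Y	15500001	59373566	Yq	gneg
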