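# Built-in organism reference catalog: id, display name, species, build, chromosome table, optional cytoband table
# columns: id	display_name	species	build	chrom_file	cytoband_file
human	Human	H. sapiens	GRCh37.p11	human.tsv	human_cytoband_synthetic.tsv
fly	Fly	D. melanogaster	BDGP5	fly.tsv	-
mouse	Mouse	M. musculus	GRCm38.p1	mouse.tsv	-
worm	Worm	C. elegans	WBcel235	worm.tsv	-
yeast	Yeast	S. cerevisiae	EF4	yeast.tsv	-
zebrafish	Zebra fish	D. rerio	Zv9	zebrafish.tsv	-
arabidopsis	Arabidopsis	A. thaliana	TAIR10	arabidopsis.tsv	-
rice	Rice	O. sativa	MSU6	rice.tsv	-
tomato	Tomato	S. lycopersicum	SL2.40	tomato.tsv	-
ecoli	E. Coli	K-12	MG1655	ecoli.tsv	-
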