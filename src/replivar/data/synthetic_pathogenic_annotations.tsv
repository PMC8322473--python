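# Synthetic COSMIC-like pathogenicity table (hg19-style representative
# coordinates) covering the pancreatic-cancer hotspot variants the cohort
# fixtures reference. Coordinates are representative fixture values, not a
# database export.
chrom	pos	ref	alt	gene	cdna	protein	classification	tissue
chr12	25398284	C	T	KRAS	c.35G>A	p.G12D	pathogenic	pancreas,lung,large_intestine
chr12	25398285	C	G	KRAS	c.34G>C	p.G12R	pathogenic	pancreas
chr12	25398281	C	T	KRAS	c.38G>A	p.G13D	pathogenic	pancreas,large_intestine
chr12	25380277	G	T	KRAS	c.181C>A	p.Q61K	pathogenic	pancreas
chr17	7578265	G	A	TP53	c.586C>T	p.R196X	pathogenic	pancreas,breast
chr17	7577094	G	A	TP53	c.844C>T	p.R282W	pathogenic	pancreas,ovary
chr18	48591918	G	A	SMAD4	c.1082G>A	p.R361H	pathogenic	pancreas
chr2	29443631	G	A	ALK	c.3257C>T	p.S1086L	likely-pathogenic	pancreas
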