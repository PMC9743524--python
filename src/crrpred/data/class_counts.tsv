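genome	cell_line	label	count	in_grand_total
hg19	HepG2	AE	1465	1
hg19	HepG2	IE	34556	1
hg19	HepG2	AP	11467	1
hg19	HepG2	IP	96184	1
hg19	HepG2	AX	9931	1
hg19	HepG2	IX	19071	1
hg19	HepG2	UK	79417	1
hg19	K562	AE	894	1
hg19	K562	IE	34392	1
hg19	K562	AP	10076	1
hg19	K562	IP	82829	1
hg19	K562	AX	9033	1
hg19	K562	IX	20261	1
hg19	K562	UK	78081	1
hg19	GM12878	AE	2878	1
hg19	GM12878	IE	28156	1
hg19	GM12878	AP	10816	1
hg19	GM12878	IP	73891	1
hg19	GM12878	AX	8226	1
hg19	GM12878	IX	19078	1
hg19	GM12878	UK	80004	1
hg19	HelaS3	AE	1847	0
hg19	HelaS3	IE	32179	0
hg19	HelaS3	AP	10759	0
hg19	HelaS3	IP	79004	0
hg19	HelaS3	AX	9123	0
hg19	HelaS3	IX	22071	0
hg19	HelaS3	UK	81502	0
hg38	HepG2	AE	7177	1
hg38	HepG2	IE	56108	1
hg38	HepG2	AP	14092	1
hg38	HepG2	IP	85789	1
hg38	K562	AE	5524	1
hg38	K562	IE	57761	1
hg38	K562	AP	12524	1
hg38	K562	IP	87357	1
hg38	GM12878	AE	11589	1
hg38	GM12878	IE	51696	1
hg38	GM12878	AP	14036	1
hg38	GM12878	IP	85845	1
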