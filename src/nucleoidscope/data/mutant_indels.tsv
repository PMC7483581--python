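chrom	pos	ref	alt	effect	product	differential_expression
chr1	949225	T	TG	Frameshift insertion	Endopeptidase La	No
chr1	1407524	A	AAT	Frameshift insertion	DUF2163 domain-containing protein	Down (fold change = 3.1)
chr1	1407524	-	AT	Frameshift insertion	Hypothetical protein	Down (fold change = 2.7)
chr1	1407835	G	-	Frameshift deletion	Hypothetical protein	Down (fold change = 2.7)
chr1	1407841	AA	-	Frameshift deletion	Hypothetical protein	Down (fold change = 2.7)
chr1	1407844	-	GCA	Non-frameshift insertion	Hypothetical protein	Down (fold change = 2.7)
chr1	1407867	-	C	Frameshift insertion	Hypothetical protein	Down (fold change = 2.7)
chr1	1407871	-	CA	Frameshift insertion	Hypothetical protein	Down (fold change = 2.7)
chr1	1407874	TCTG	-	Frameshift deletion	Hypothetical protein	Down (fold change = 2.7)
chr1	1407878	-	AG	Frameshift insertion	Hypothetical protein	Down (fold change = 2.7)
chr1	1407881	C	-	Frameshift deletion	Hypothetical protein	Down (fold change = 2.7)
chr1	1408385	-	CT	Frameshift insertion	Hypothetical protein	Down (fold change = 2.7)
chr1	1408388	-	AC	Stopgain SNV	Hypothetical protein	Down (fold change = 2.7)
chr1	1408392	TCAG	-	Frameshift deletion	Hypothetical protein	Down (fold change = 2.7)
chr1	1412115	-	G	Frameshift insertion	Hypothetical protein	Down (fold change = 2.7)
chr1	1412117	CC	-	Frameshift deletion	Hypothetical protein	Down (fold change = 2.7)
chr1	1939661	CGCCACTT	-	-	Upstream: class I SAM-dependent methyltransferase; GNAT family N-acetyltransferase	No
chr1	1939672	CTAA	-	-	Upstream: class I SAM-dependent methyltransferase; GNAT family N-acetyltransferase	No
chr1	1939679	ATT	-	-	Upstream: class I SAM-dependent methyltransferase; GNAT family N-acetyltransferase	No
chr1	1939682	-	A	-	Upstream: class I SAM-dependent methyltransferase; GNAT family N-acetyltransferase	No
chr1	1939687	GT	-	-	Upstream: class I SAM-dependent methyltransferase; GNAT family N-acetyltransferase	No
chr1	1939690	AACACTTAAG	-	-	Upstream: class I SAM-dependent methyltransferase; GNAT family N-acetyltransferase	No
chr1	1939703	ATT	-	-	Upstream: class I SAM-dependent methyltransferase; GNAT family N-acetyltransferase	No
chr2	1230228	GAATAGACAACCTTTTGTCCTTTCTGATGATTAATAGATAGGCTCATATATTGTTACATTCATTCT	-	-	Downstream: ABC transporter ATP-binding protein; hypothetical protein; DUF3346 domain-containing protein	No
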