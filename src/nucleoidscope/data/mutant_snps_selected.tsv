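chrom	pos	ref	alt	effect	product	differential_expression
chr1	676480	G	T	Non-synonymous SNV	Ubiquinone-binding protein	No
chr1	1939654	A	G	-	Upstream: class I SAM-dependent methyltransferase; GNAT family N-acetyltransferase	No
chr1	1939655	C	T	-	Upstream: class I SAM-dependent methyltransferase; GNAT family N-acetyltransferase	No
chr1	1990799	A	G	Non-synonymous SNV	Methyl-accepting chemotaxis protein	No
chr1	2328261	G	A	Non-synonymous SNV	Chemotaxis protein CheA	No
chr2	257319	C	T	Non-synonymous SNV	DUF3404 domain-containing protein	No
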