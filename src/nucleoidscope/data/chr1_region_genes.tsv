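gene_id	start	end	differential_expression	product
BA890_RS06375	1393096	1394310	Down	DNA integration; DNA binding; DNA recombination
BA890_RS06395	1397787	1399340	Down	Phage portal protein
BA890_RS06385	1395452	1397266	Down	Phage terminase large subunit family protein
BA890_RS06400	1399312	1401282	Down	Major capsid protein
BA890_RS06425	1402873	1403373	Down	Tail protein
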