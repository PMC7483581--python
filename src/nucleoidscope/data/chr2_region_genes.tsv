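gene_id	start	end	differential_expression	product
BA890_RS15740	191107	192813	Up	D-Lactate dehydrogenase
BA890_RS15855	214252	215001	Up	Siderophore ferric iron reductase
BA890_RS15900	223502	224332	Up	Formate dehydrogenase family accessory protein FdhD
BA890_RS15905	224373	225254	Up	LysR family transcriptional regulator
BA890_RS15910	225884	228208	Up	CbbBc protein
BA890_RS15825	209062	209385	Down	Nitrite reductase small subunit
BA890_RS15830	209573	210421	Up	Formate transporter
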