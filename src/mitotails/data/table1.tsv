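accession	protein_name	nterm_peptide	p_prime_position	mtTP	chain
Q9BW92	Threonine-tRNA ligase	LHTAVVSTPPR	20	1-19	20-718
P82673	28S ribosomal protein S35	STAVYSATPVPTPSLPER	23	1-22	23-323
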