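# Whole-genome bacterial evolution-experiment datasets with known numbers
# of generations, for cross-study comparison of simple rate estimates.
# synonymous_sites is the one-third-of-coding-bp approximation computed
# from each ancestral genome annotation; the ltee row pools the designated
# per-population end-point clones (25 synonymous mutations in 8 clones) to
# keep clones independent, as in the other studies.
study	strain	clones	cumulative_generations	synonymous_sites	synonymous_mutations	genome_size_bp
ltee	Escherichia coli B REL606	19	300000	941000	25	4600000
mg1655	Escherichia coli K-12 MG1655	12	10700	930000	5
w3110	Escherichia coli W3110	4	13850	945000	2
lt2	Salmonella typhimurium LT2	1	5000	990000	2
dk1622	Myxococcus xanthus DK1622	1	1000	2140000	1
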