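# Eight-species eutherian panel: Tex19 (copies_a) and Sectm1 (copies_b)
# gene copy numbers; complete_genome marks finished genome assemblies.
species	copies_a	copies_b	complete_genome
Dasypus_novemcinctus	0	1	False
Homo_sapiens	1	1	True
Pan_troglodytes	1	1	True
Macaca_mulatta	1	1	False
Cavia_porcellus	1	1	False
Mus_musculus	2	2	True
Rattus_norvegicus	2	2	False
Bos_taurus	2	2	False
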