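chrom	length	centromere
chr1	248956422	123400000
chr2	242193529	93900000
chr3	198295559	90900000
chr4	190214555	50000000
chr5	181538259	48800000
chr6	170805979	59800000
chr7	159345973	60100000
chr8	145138636	45200000
chr9	138394717	43000000
chr10	133797422	39800000
chr11	135086622	53400000
chr12	133275309	35500000
chr13	114364328	17700000
chr14	107043718	17200000
chr15	101991189	19000000
chr16	90338345	36800000
chr17	83257441	25100000
chr18	80373285	18500000
chr19	58617616	26200000
chr20	64444167	28100000
chr21	46709983	12000000
chr22	50818468	15000000
chrX	156040895	60600000
chrY	57227415	10400000
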