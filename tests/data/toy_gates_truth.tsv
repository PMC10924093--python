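snp	pass_genomewide	pass_direction	pass_replication	pass_de	af_shortlisted	af_reportable
rs1	1	1	1	1	1	1
rs2	1	0	0	1	1	0
rs3	0	1	1	0	0	0
rs4	0	0	0	1	1	1
rs5	1	1	1	1	1	0
rs6	0	0	0	0	0	0
rs7	1	1	1	0	1	0
rs8	0	1	0	1	1	1
rs9	0	0	1	1	1	1
rs10	1	1	0	0	1	0
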