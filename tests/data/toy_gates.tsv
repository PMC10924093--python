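snp	p	beta_egfr	beta_bun	p_rep1	p_rep2	log2fc	p_de	af_cohort	af_ref
rs1	1e-9	0.02	-0.03	0.01	0.04	1.5	0.001	0.50	0.30
rs2	4.9e-8	0.02	0.03	0.01	0.06	-1.2	0.002	0.42	0.30
rs3	5.1e-8	-0.02	0.03	0.04	0.04	0.8	0.0005	0.35	0.30
rs4	5e-8	0.0	-0.03	0.06	0.01	1.0	0.004	0.10	0.30
rs5	1e-12	-0.5	0.5	0.001	0.001	-1.0	0.01	0.44	0.30
rs6	0.2	-0.1	-0.2	0.2	0.01	2.0	0.5	0.30	0.30
rs7	1e-8	0.01	-0.01	0.049	0.049	0.0	0.9	0.20	0.31
rs8	0.04	0.3	-0.2	0.05	0.01	1.1	0.03	0.80	0.55
rs9	1e-7	0.2	0.1	0.01	0.01	-3.0	0.0001	0.05	0.30
rs10	2e-8	-0.04	0.05	0.01	0.051	1.4	0.2	0.13	0.02
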