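# Demo reference alt-allele frequencies for three continental populations.
# These are plausible testing values, NOT authoritative database frequencies;
# supply real population tables for production use.
# Columns: population, rsid, alt_freq, sample_size
population	rsid	alt_freq	sample_size
CEU	rs1799853	0.12	180
CEU	rs1057910	0.07	180
CEU	rs4244285	0.15	180
CEU	rs4986893	0.005	180
CEU	rs28399504	0.002	180
CEU	rs12248560	0.22	180
CEU	rs35742686	0.02	180
CEU	rs3892097	0.20	180
CEU	rs5030655	0.01	180
CEU	rs5030656	0.02	180
CEU	rs1065852	0.23	180
CEU	rs28371725	0.09	180
CEU	rs7668258	0.49	180
CEU	rs1051740	0.30	180
CEU	rs2234922	0.20	180
CEU	rs4713916	0.30	180
CEU	rs1800497	0.20	180
CEU	rs1799978	0.05	180
CEU	rs963468	0.33	180
CEU	rs1414334	0.16	180
CEU	rs17782313	0.24	180
CEU	rs489693	0.27	180
CEU	rs2832407	0.42	180
CEU	rs3812718	0.47	180
YRI	rs1799853	0.02	180
YRI	rs1057910	0.01	180
YRI	rs4244285	0.17	180
YRI	rs4986893	0.005	180
YRI	rs28399504	0.002	180
YRI	rs12248560	0.25	180
YRI	rs35742686	0.005	180
YRI	rs3892097	0.08	180
YRI	rs5030655	0.003	180
YRI	rs5030656	0.005	180
YRI	rs1065852	0.12	180
YRI	rs28371725	0.02	180
YRI	rs7668258	0.25	180
YRI	rs1051740	0.15	180
YRI	rs2234922	0.18	180
YRI	rs4713916	0.18	180
YRI	rs1800497	0.42	180
YRI	rs1799978	0.12	180
YRI	rs963468	0.65	180
YRI	rs1414334	0.45	180
YRI	rs17782313	0.26	180
YRI	rs489693	0.30	180
YRI	rs2832407	0.85	180
YRI	rs3812718	0.25	180
CHB	rs1799853	0.01	90
CHB	rs1057910	0.04	90
CHB	rs4244285	0.31	90
CHB	rs4986893	0.06	90
CHB	rs28399504	0.005	90
CHB	rs12248560	0.02	90
CHB	rs35742686	0.005	90
CHB	rs3892097	0.01	90
CHB	rs5030655	0.002	90
CHB	rs5030656	0.002	90
CHB	rs1065852	0.57	90
CHB	rs28371725	0.03	90
CHB	rs7668258	0.27	90
CHB	rs1051740	0.48	90
CHB	rs2234922	0.12	90
CHB	rs4713916	0.24	90
CHB	rs1800497	0.40	90
CHB	rs1799978	0.10	90
CHB	rs963468	0.40	90
CHB	rs1414334	0.12	90
CHB	rs17782313	0.22	90
CHB	rs489693	0.25	90
CHB	rs2832407	0.60	90
CHB	rs3812718	0.42	90
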