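sample_id	age	sex	rs1051740	rs1057910	rs1065852	rs12248560	rs1414334	rs17782313	rs1799853	rs1799978	rs1800497	rs2234922	rs2832407	rs28371725	rs28399504	rs35742686	rs3812718	rs3892097	rs4244285	rs4713916	rs489693	rs4986893	rs5030655	rs5030656	rs7668258	rs963468
case_a	19	male	TT	AA	GG	CC	CC	TT	CC	TT	GG	AA	CC	GG	AA	AA	GG	CC	AA	GG	AA	GG	TT	AA	TT	AA
case_b	30	female	TT	AA	GG	CC	CG	TC	CC	TT	GG	AA	CC	GG	AA	AA	GG	CC	GG	GG	AA	GG	TT	AA	TT	AA
case_c	56	female	TT	AA	GG	CT	CC	TT	CC	TT	GG	AA	CC	GG	AA	AA	GG	CC	GA	GG	AA	GG	TT	AA	TT	AA
case_d	49	male	TT	AA	GA	CC	CC	TT	CC	TT	GG	AA	CC	GG	AA	AA	GG	CT	GA	AA	AA	GG	TT	AA	TT	AA
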