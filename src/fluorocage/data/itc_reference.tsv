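label	kd_nM	kd_err_nM	delta_g	delta_g_err	delta_h	delta_h_err	minus_t_delta_s	minus_t_delta_s_err	temperature_K
BL21_WT	54	6	-9.9	0.1	-11.6	0.1	1.7	0.2	298.15
AUX_WT	48	8	-10.0	0.1	-11.9	0.1	1.9	0.1	298.15
5F	49	12	-10.0	0.1	-10.9	0.1	0.9	0.3	298.15
6F	57	17	-9.9	0.2	-12.1	0.1	2.2	0.3	298.15
56diF	70	15	-9.8	0.1	-11.7	0.2	1.9	0.3	298.15
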