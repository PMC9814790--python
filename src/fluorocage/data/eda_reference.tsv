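label	e_aq	e_aq_strain	e_aq_int	e_desolv_int	e_int	e_pauli	v_elstat	e_oi	e_disp	d_hme_c6mr	d_hme_c5mr
WT	-10.2	0.1	-10.3	17.3	-27.6	20.8	-15.0	-13.0	-20.4	3.38	2.78
5F	-10.4	0.3	-10.7	14.5	-25.2	20.4	-12.2	-12.8	-20.5	3.50	2.70
6F	-10.3	0.3	-10.6	14.0	-24.6	21.0	-12.0	-13.0	-20.5	3.54	2.68
56diF	-10.3	0.3	-10.6	11.7	-22.3	19.8	-9.0	-12.6	-20.5	3.52	2.70
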