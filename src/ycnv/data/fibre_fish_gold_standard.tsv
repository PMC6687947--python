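sample_id	haplogroup	region_1	region_2	region_3	region_4	total_fibre_fish	cn_read_depth	cn_ddpcr
HG02141	C3f-F2613	4	7	1	1	13	12.9	12.9
HG01699	E1b1b1b1-L19	6	2	1	1	10	10.7	9.8
HG02224	G2a3-L30	4	3	1	2	10	10.9	10.4
HG02789	G2b1-M283	4	3	1	1	9	9.5	8.2
HG02020	O2a1a-M88	4	5	1	1	11	10.5	10.8
HG02032	O2a1a-M88	4	2	1	1	8	8.4	7.8
HG00704	O3a2b1-M188	5	2	1	1	9	8.7	8.8
HG00692	O3a2b1-M188	3	2	1	1	7	7.0	6.8
NA19774	Q1a2a1-L54	6	1	1	1	9	8.9	8.5
HG01977	Q1a2a1a1-M3	5	4	1	1	11	10.4	10.7
HG01938	Q1a2a1a1-M3	2	2	1	1	6	6.6	6.3
HG03652	Q1b-F711	2	1	1	1	5	5.1	5.2
HG03899	R1a1a1b2a1-L657	5	4	1	1	11	12.0	10.5
NA10851	R1b1a2a1a2c1i-CTS6581	2	2	1	1	6	5.7	5.8
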