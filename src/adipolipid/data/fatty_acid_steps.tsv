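name	enzyme	substrate_fa	product_fa	series
SCD_16	SCD	16:0	16:1n7	n-7
SCD_18	SCD	18:0	18:1n9	n-9
ELOVL6_16_0	ELOVL6	16:0	18:0	saturated
ELOVL6_16_1n7	ELOVL6	16:1n7	18:1n7	n-7
D6D_n6	FADS2	18:2n6	18:3n6	n-6
ELOVL5_n6	ELOVL5	18:3n6	20:3n6	n-6
D5D_n6	FADS1	20:3n6	20:4n6	n-6
ELOVL_20_4n6_to_22_4n6	ELOVL2/4	20:4n6	22:4n6	n-6
D6D_n3	FADS2	18:3n3	18:4n3	n-3
ELOVL5_n3	ELOVL5	18:4n3	20:4n3	n-3
D5D_n3	FADS1	20:4n3	20:5n3	n-3
ELOVL_20_5n3_to_22_5n3	ELOVL2/5	20:5n3	22:5n3	n-3
D6D_22_5n3_to_22_6n3	FADS2	22:5n3	22:6n3	n-3
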