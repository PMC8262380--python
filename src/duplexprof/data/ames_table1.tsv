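group	chemical	dose_ug_per_plate	mean_revertants	sd_revertants	n
Alkylating agents	MNNG	0	122.0	13.9	3
Alkylating agents	MNNG	1	154.3	3.1	3
Alkylating agents	MNNG	5	2115.0	358.6	3
Alkylating agents	MMS	0	116.0	25.2	3
Alkylating agents	MMS	30	222.7	28.9	3
Alkylating agents	MMS	1000	1956.3	116.2	3
Aldehydes	Glyoxal	0	116.0	25.2	3
Aldehydes	Glyoxal	30	472.3	45.5	3
Aldehydes	Glyoxal	60	900.0	73.0	3
Aldehydes	FA	0	133.7	9.6	3
Aldehydes	FA	10	205.0	17.6	3
Aldehydes	FA	20	223.3	7.4	3
Aromatic nitro compounds	4NQO	0	133.7	9.6	3
Aromatic nitro compounds	4NQO	0.1	851.7	41.8	3
Aromatic nitro compounds	4NQO	0.5	2181.7	263.6	3
Epoxides	Glycidol	0	134.3	9.5	3
Epoxides	Glycidol	1000	2252.3	220.7	3
Epoxides	Glycidol	10000	6492.7	936.9	3
Epoxides	PO	0	91.0	11.0	3
Epoxides	PO	5000	1363.0	92.8	3
Epoxides	PO	10000	1655.3	20.6	3
Aromatic amines	2-AA	0	112.3	7.5	3
Aromatic amines	2-AA	5	1265.0	154.3	3
Aromatic amines	2-AA	7	3131.3	141.9	3
Aromatic amines	2-AAF	0	112.3	7.5	3
Aromatic amines	2-AAF	40	1464.3	761.3	3
Aromatic amines	2-AAF	80	3903.7	108.6	3
Aromatic amines	2-AAF	120	4276.3	710.0	3
PAHs	3MC	0	100.7	10.0	3
PAHs	3MC	20	1510.7	27.5	3
PAHs	3MC	100	1618.3	155.1	3
PAHs	DMBA	0	100.7	10.0	3
PAHs	DMBA	10	707.3	23.2	3
PAHs	DMBA	20	1499.7	184.1	3
PAHs	DMBA	100	853.0	64.6	3
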