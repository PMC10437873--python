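sample_id	cell	photosynthate	province	sample_type	temperature	pH	cell_fraction
RS17S	2303.35	7311.38	Costa Rica outer forearc	Sediment	29.4	9.96	0.24
PG17S	2717.43	7824.97	Active volcanic arc	Sediment	19.2		0.26
BQ217S	275.26	702.8	Active volcanic arc	Sediment	88.9	2.11	0.28
FA17S	1356.01	3157.92	Active volcanic arc	Sediment	55.2	5.93	0.3
RS17F	1793.86	3927.14	Costa Rica outer forearc	Fluid	29.4	9.96	0.31
LE18S	1779.26	3744.37	Cordillera Talamanca	Sediment	34.7		0.32
BR117S	1790.83	3507.56	Active volcanic arc	Sediment	53.8	5.87	0.34
SL17S	1608.47	2395.79	Active volcanic arc	Sediment	57	6.12	0.4
SC18S	4231.4	5974.49	Panama slab window	Sediment	29.9	6.5	0.41
IN19S	1951.11	2651.99	Argentina backarc	Sediment	46.9	6.52	0.42
CY17S	2782.04	3678.12	Active volcanic arc	Sediment	72	6.31	0.43
BR317F	2259.54	2880.35	Active volcanic arc	Fluid	59	6.16	0.44
PP19S	2768.98	3466.71	Argentina backarc	Sediment	54.3	8.47	0.44
YR18F	3699.46	4556.12	Cordillera Talamanca	Fluid	26	8.9	0.45
RC18S	3124.49	3563.44	Cordillera Talamanca	Sediment	60	7.7	0.47
GA19S	3880.17	4421.99	Argentina backarc	Sediment	67	6.7	0.47
CW18F	16280.11	18463.25	Active volcanic backarc	Fluid	35	7.19	0.47
IN19F	4897.84	5482.85	Argentina backarc	Fluid	46.9	6.52	0.47
GF219S	8.21	8.62	Argentina backarc	Sediment	80	3.21	0.49
CW18S	1102.96	1140.82	Active volcanic backarc	Sediment	35	7.19	0.49
ET17S	3686.85	3635.11	Active volcanic arc	Sediment	40	6.06	0.5
BR217S	3714.33	3629.83	Active volcanic arc	Sediment	53.8	5.87	0.51
LH18S	8995.25	8393.51	Cordillera Talamanca	Sediment	55.4	6.7	0.52
SL17F	2882.97	2547.03	Active volcanic arc	Fluid	57	6.12	0.53
PM19S	4557.13	3980.86	Argentina backarc	Sediment	50.3	6.53	0.53
CV18S	2364.68	1971.3	Panama slab window	Sediment	34.9	7.46	0.55
RF19S	2319.97	1777.15	Argentina backarc	Sediment	82	8.23	0.57
GE18S	2650.99	1939.12	Cordillera Talamanca	Sediment	35.8	7.8	0.58
LC19S	4152.17	3007.55	Argentina backarc	Sediment	84	6.94	0.58
PF17S	5696.03	4077.12	Active volcanic backarc	Sediment	28.7	5.81	0.58
SI17S	3655.49	2607.84	Costa Rica outer forearc	Sediment	35.9	9.83	0.58
MC18S	7088.09	5020.36	Cordillera Talamanca	Sediment	31.8	9.6	0.59
HV121S	5.04	3.52	Spreading center hot spot	Sediment	93.5	2.72	0.59
EP17S	4095.65	2760.82	Costa Rica outer forearc	Sediment	26.4	9.99	0.6
AR17S	1015.94	613.94	Active volcanic arc	Sediment			0.62
PF17F	5945.38	3326.85	Active volcanic backarc	Fluid	28.7	5.81	0.64
GA19F	3232.45	1772.08	Argentina backarc	Fluid	67	6.7	0.65
LB18S	1799.92	907.5	Panama slab window	Sediment	34.8	5.951	0.66
RR18F	2427.99	1216.93	Cordillera Talamanca	Fluid	41.3	7.2756	0.67
BR117F	5777.06	2784.88	Active volcanic arc	Fluid	59	6.16	0.67
PX18S	7241.69	3328.99	Active volcanic backarc	Sediment	42.9225	6.3077	0.69
XF18S	1378.69	617.31	Active volcanic backarc	Sediment	28.9	7	0.69
CH18S	1497.87	644.82	Panama slab window	Sediment	31.1	7	0.7
QN17S	8016.9	3343.38	Active volcanic arc	Sediment	22.9	5.6	0.71
VV19F	4672.04	1821.79	Argentina backarc	Fluid	38.2	9.09	0.72
SC18F	6730.07	2555.04	Panama slab window	Fluid	29.9	6.5	0.72
BC18F	3840.09	1452.1	Panama slab window	Fluid	31.8	7.5	0.73
CI18S	10418.56	3918.02	Panama slab window	Sediment	48.3	9	0.73
BS18F	9438.61	3449.51	Cordillera Talamanca	Fluid	40.9	9.05	0.73
TC17S	11507.98	4132.12	Active volcanic arc	Sediment	60	6.24	0.74
ER18F	4408.88	1580.28	Active volcanic backarc	Fluid	35	9.51	0.74
TC17F	6889.35	2454.24	Active volcanic arc	Fluid	60	6.24	0.74
BQ117F	4.55	1.61	Active volcanic arc	Fluid	88.9	2.11	0.74
LB18F	6797.71	2293.94	Panama slab window	Fluid	34.8	5.951	0.75
QH217S	5764.17	1913.66	Costa Rica outer forearc	Sediment	36.7	8.69	0.75
CL18F	10123.52	3243.36	Panama slab window	Fluid	50.9	7.5	0.76
MT17F	7584.31	2352.33	Active volcanic arc	Fluid	59.1	6.32	0.76
CY17F	5257.73	1501	Active volcanic arc	Fluid	72	6.31	0.78
TM19S	10956.68	3105.54	Argentina backarc	Sediment	69.2	7.13	0.78
QH117S	5565.26	1527.88	Costa Rica outer forearc	Sediment	36.7	8.69	0.78
GF119S	7954.31	2174.13	Argentina backarc	Sediment	80	7.75	0.79
LH18F	11274.13	3025.97	Cordillera Talamanca	Fluid	55.4	6.7	0.79
EP17F	3224.4	850.89	Costa Rica outer forearc	Fluid	26.4	9.99	0.79
AO19S	315.56	82.69	Argentina backarc	Sediment	27.8	6.25	0.79
LC19F	7355.95	1836.67	Argentina backarc	Fluid	84	6.94	0.8
PG19S	5290.06	1307.15	Argentina backarc	Sediment	43.9	8.74	0.8
PS18S	1165.03	286.77	Costa Rica outer forearc	Sediment	33	8.2	0.8
PL17S	20079.51	4798.48	Active volcanic arc	Sediment	37.6	0.85	0.81
LE18F	5406.9	1289.32	Cordillera Talamanca	Fluid	34.7		0.81
BJ19S	2057.82	474.15	Argentina backarc	Sediment	40	6.44	0.81
LP18F	8018.62	1783.25	Cordillera Talamanca	Fluid	39.1	6.5	0.82
GF219F	25.72	5.37	Argentina backarc	Fluid	80	3.21	0.83
ER18S	7225.99	1464.14	Active volcanic backarc	Sediment	35	9.51	0.83
QH217F	4871.79	978.15	Costa Rica outer forearc	Fluid	48.7	8.53	0.83
HV221S	142.26	28.35	Spreading center hot spot	Sediment	25.7	1.82	0.83
MC18F	7154.79	1377.19	Cordillera Talamanca	Fluid	31.8	9.6	0.84
XF18F	11532.69	2192.06	Active volcanic backarc	Fluid	28.9	7	0.84
PG17F	917.39	169.35	Active volcanic arc	Fluid	19.2		0.84
LW18S	2907.58	491.44	Costa Rica outer forearc	Sediment	31.5	7.1	0.86
HA18F	5644.82	936.25	Cordillera Talamanca	Fluid	33	8.9	0.86
BR217F	12377.42	1729.54	Active volcanic arc	Fluid	59	6.16	0.88
PM19F	10782.76	1501.85	Argentina backarc	Fluid	50.3	6.53	0.88
AO19F	399.1	54.82	Argentina backarc	Fluid	27.8	6.25	0.88
GF119F	12.49	1.69	Argentina backarc	Fluid	80	7.75	0.88
BW18F	3514.44	451.47	Cordillera Talamanca	Fluid	43.2	9.05	0.89
BQ217F	3.79	0.44	Active volcanic arc	Fluid	88.9	2.11	0.9
LW18F	14067.82	1595.78	Costa Rica outer forearc	Fluid	31.5	7.1	0.9
QN17F	6016.9	676.83	Active volcanic arc	Fluid	22.9	5.6	0.9
CH18F	4852.63	515.69	Panama slab window	Fluid	31.1	7	0.9
CV18F	9161.27	951.7	Panama slab window	Fluid	34.9	7.46	0.91
CZ18F	16531	1610.23	Panama slab window	Fluid	26.3	10	0.91
RC18S	5817.55	391.52	Cordillera Talamanca	Fluid	60	7.7	0.94
PG19F	8315.79	515.92	Argentina backarc	Fluid	43.9	8.74	0.94
PB17S	2689.73	112.99	Active volcanic arc	Sediment			0.96
CI18F	16955.03	682.48	Panama slab window	Fluid	48.3	9	0.96
RV17F	15451.3	576.05	Active volcanic arc	Fluid	42.7	6.19	0.96
ES17F	7007.89	259.52	Costa Rica outer forearc	Fluid	27.9	9.75	0.96
KR21S	61.39	1.58	Spreading center hot spot	Sediment	93	2.04	0.97
SI17F	7079.4	161.59	Costa Rica outer forearc	Fluid	35.9	9.83	0.98
BJ19F	3362.49	20.58	Argentina backarc	Fluid	40	6.44	0.99
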