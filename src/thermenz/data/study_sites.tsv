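abbrev	sample_name	site_name	region	latitude	longitude	province	temperature	pH
AO19	AO190224	Antuco	Argentina	-24.182136	-66.674029	Argentina backarc	27.8	6.3
AR17	AR170220	Arenal Horse Farm	Costa Rica	10.4864	-84.6872	Costa Rica active volcanic arc	NM	NM
BC18	BC180410	Los Bajos the Corera	Panama	8.806037	-79.790968	Panama slab window	31.8	7.5
BJ19	BJ190227	Botijuela	Argentina	-25.743034	-67.823245	Argentina backarc	40	6.4
BQ17	BQ170218	Borinquen	Costa Rica	10.810883	-85.413707	Costa Rica active volcanic arc	88.9	2.1
BR117	BR170218_1	Blue River Spring 1	Costa Rica	10.89837	-85.32839	Costa Rica active volcanic arc	59	6.2
BR217	BR170218_2	Blue River Spring 2	Costa Rica	10.89837	-85.32853	Costa Rica active volcanic arc	53.8	5.9
BS18	BS180407	Bajo Mendez Spring	Costa Rica	8.66645	-82.3491	Cordillera Talamanca-Chiriquí	40.9	9.1
BW18	BW180407	Bajo Mendez Well	Costa Rica	8.66581	-82.34867	Cordillera Talamanca-Chiriquí	43.2	9.1
CH18	CH180410	Chiguiri Abajo	Panama	8.70508	-80.26919	Panama slab window	31.1	7
CI18	CI180408	Coiba Island	Panama	7.44104	-81.73277	Panama slab window	48.3	9
CL18	CL180409	Calobre	Panama	8.40448	-80.80375	Panama slab window	50.9	7.5
CV18	CV180410	Casa Valmor	Panama	8.5992	-80.13162	Panama slab window	34.9	7.5
CW18	CW180415	Cauhita Well	Costa Rica	9.735746	-82.825737	Costa Rica backarc	35	7.2
CY17	CY170214	Rio Cayuco	Costa Rica	10.287497	-84.955524	Costa Rica active volcanic arc	72	6.3
CZ18	CZ180409	Salitral Carrizal	Panama	7.71407	-81.28832	Panama slab window	26.3	10
EP17	EP170215	Espabel	Costa Rica	9.901885	-85.454327	Costa Rica outer forearc	26.4	9.9
ES17	ER180415	Rio Blanco Er Resbala	Costa Rica	9.938223	-83.161331	Costa Rica backarc	35	9.5
ER18	ES170215_1	Estrada	Costa Rica	9.899005	-85.453514	Costa Rica outer forearc	27.9	9.7
ET17	ET170220_1	Eco Thermales	Costa Rica	10.484006	-84.675853	Costa Rica active volcanic arc	40	6.1
FA17	FA170219_1	Finca Ande	Costa Rica	10.336843	-85.069499	Costa Rica active volcanic arc	55.2	5.9
GA19	GA190226	Galán Aguas Calientes	Argentina	-25.825416	-66.922496	Argentina backarc	67	6.7
GE18	GE180403	Gevi	Costa Rica	9.19483333	-83.280806	Cordillera Talamanca-Chiriquí	35.8	7.8
GF119	GF190226_1	Galán Fumaroles 1	Argentina	-25.858188	-66.992695	Argentina backarc	80	7.8
GF219	GF190226_2	Galán Fumaroles 2	Argentina	-25.858243	-66.992818	Argentina backarc	80	3.2
HA18	HA180403	Hattillo	Costa Rica	9.36022	-83.91664	Cordillera Talamanca-Chiriquí	33	8.9
HV121	HV1210602	Hveragerdi 1	Iceland	64.008117	-21.17949	Iceland spreading center	93.5	2.7
HV221	HV2210602	Hveragerdi 2	Iceland	64.007062	-21.180739	Iceland spreading center	25.7	1.8
IN19	IN190223	Incachule	Argentina	-24.282129	-66.466761	Argentina backarc	46.9	6.5
KR21	KR2210530	Krysuvik upper pool	Iceland	63.895451	-22.057004	Iceland spreading center	93	2
LB18	LB180410	Los Bajos	Panama	8.80736	-79.79061	Panama slab window	34.8	NM
LC19	LC190226	Galán La Colcha	Argentina	-26.032911	-66.986094	Argentina backarc	84	6.9
LE18	LE180416	Las Estrella	Costa Rica	10.427103	-84.368543	Cordillera Talamanca-Chiriquí	34.7	NM
LH18	LH180406	Los Pozos Thermales	Panama	8.87095	-82.6899	Cordillera Talamanca-Chiriquí	55.4	6.7
LP18	LP180406	Los Pozos Thermales	Panama	8.86966	-82.69282	Cordillera Talamanca-Chiriquí	39.1	6.5
LW18	LW180405	Laurel	Costa Rica	8.44119	-82.90487	Costa Rica outer forearc	31.5	7.1
MC18	MC180404	Montecarlo—Bernardino	Costa Rica	9.34391	-83.59565	Cordillera Talamanca-Chiriquí	31.8	9.6
MT17	MT170219	Termales Salitral	Costa Rica	10.595774	-85.238451	Costa Rica active volcanic arc	59.1	6.3
PB17	PB170224	Poas Volcano background soil	Costa Rica	10.196777	-84.229892	Costa Rica active volcanic arc	NM	NM
PF17	PF170222	Pompilo’s finca	Costa Rica	10.518466	-84.11518	Costa Rica backarc	28.7	5.8
PG19	PG190225	Pastos Grandes	Argentina	-24.364589	-66.571132	Argentina backarc	44.9	8.7
PG17	PG172224	Poas Volcano Laguna	Costa Rica	10.188962	-84.227388	Costa Rica active volcanic arc	19.2	NM
PL17	PL170224	Poas Volcano Lake	Costa Rica	10.196777	-84.229892	Costa Rica active volcanic arc	37.6	0.8
PM19	PM190223	Pompeya	Argentina	-24.246688	-66.362722	Argentina backarc	50.3	6.5
PP19	PP190301	El Galpón Pio Perez	Argentina	-24.40986	-64.59146	Argentina backarc	54.3	8.5
PS18	PS180405	Playa Sandalo	Costa Rica	8.57554	-83.36416	Costa Rica outer forearc	33	8.2
PX18	PX180416	Praxair well 24	Costa Rica	10.488755	-84.113598	Costa Rica backarc	28.7	NM
QH117	QH170213_1	Quepos Hot springs	Costa Rica	9.56171	-84.123251	Costa Rica outer forearc	48.7	8.5
QH217	QH170213_2	Quepos Hot springs	Costa Rica	9.561575	-84.123468	Costa Rica outer forearc	36.7	8.7
QN17	QN170220	Quebrada naranja	Costa Rica	10.495573	-84.696714	Costa Rica active volcanic arc	22.9	5.6
RC18	RC180404	Ujarassa	Costa Rica	9.30283	-83.29782	Cordillera Talamanca-Chiriquí	60	7.7
RF19	RF190301	Rosario de la Frontera	Argentina	-25.40986	-64.59134	Argentina backarc	82	8.2
RR18	RR180407	"Rockslide"	Costa Rica	8.63591	-82.22369	Cordillera Talamanca-Chiriquí	41.3	NM
RS17	RS170216	Ranchero etl Salitral	Costa Rica	10.232331	-85.531602	Costa Rica outer forearc	29.4	9.9
RV17	RV170221	Recreo Verde	Costa Rica	10.321576	-84.243686	Costa Rica active volcanic arc	42.7	6.2
SC18	SC180411	El Salao Campollano	Panama	8.15755	-81.13097	Panama slab window	29.9	7
SI17	SI170217	El Sitio	Costa Rica	10.301239	-85.610549	Costa Rica outer forearc	35.9	9.8
SL17	SL170214	Santa Lucia	Costa Rica	10.290599	-84.972435	Costa Rica active volcanic arc	57	6.1
TC17	TC170221	El Tucano bubbling site	Costa Rica	10.366486	-84.381208	Costa Rica active volcanic arc	60	6.2
TM19	TM190224	Tocomar	Argentina	-24.18778	-66.55451	Argentina backarc	69.2	7.1
VV19	VV190228	Villa Vil	Argentina	-27.112858	-66.822241	Argentina backarc	38.2	9.1
XF18	XF180416	Praxair well 19	Costa Rica	10.485523	-84.113229	Costa Rica backarc	28.9	7
YR18	YR180404	Yheri	Costa Rica	9.19492	-83.28059	Cordillera Talamanca-Chiriquí	26	8.9
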