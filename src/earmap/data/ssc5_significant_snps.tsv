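marker	chr	pos	nearest_gene	distance	P	var_pct
ALGA0031433	5	30135149	LOC100737618	within	6.43E-08	50.24
ALGA0123559	5	30237457	LOC100737618	within	5.79E-08	50.55
ALGA0031434	5	30237479	LOC100737618	within	5.79E-08	50.55
DIAS0000998	5	30315076	LOC102158157	within	5.79E-08	50.55
MARC0087309	5	30346502	LOC102158157	7382	5.79E-08	50.55
ASGA0025209	5	30562154	LOC102158306	68986	4.33E-08	51.07
MARC0065416	5	31339549	LOC102159444	within	6.08E-08	50.81
INRA0019079	5	31568334	LOC100737829	within	3.55E-08	51.55
ALGA0031498	5	31739296	SRGAP1	within	2.92E-08	51.91
ASGA0083598	5	31787290	SRGAP1	within	6.91E-08	50.92
H3GA0016170	5	31980027	C5H12orf56	5519	5.29E-08	49.85
MARC0012331	5	32349029	TBC1D30	57423	1.90E-08	53.16
MARC0001519	5	32514953	LOC100512657	within	2.01E-07	50.56
ASGA0025237	5	32661210	WIF1	within	1.43E-08	52.97
DRGA0005606	5	32692874	WIF1	within	2.14E-08	53.08
ASGA0025238	5	32705404	WIF1	within	1.43E-08	52.97
ASGA0025241	5	32727429	WIF1	9252	9.16E-08	52.62
ALGA0031516	5	32753183	LOC102160719	4106	1.43E-08	52.97
DRGA0005608	5	32804318	LEMD3	within	1.43E-08	52.97
ASGA0025245	5	32913506	MSRB3	7238	1.43E-08	52.97
ASGA0025246	5	32965291	MSRB3	within	1.43E-08	52.97
ALGA0031519	5	33007354	MSRB3	within	2.19E-08	52.80
H3GA0016181	5	33239191	LOC102161223	33572	7.34E-09	53.09
ALGA0031527	5	33300696	HMGA2	75270	1.18E-08	53.09
DRGA0005611	5	33380452	HMGA2	within	1.18E-08	53.09
SIRI0000534	5	34023534	GRIP1	within	1.96E-08	52.21
ALGA0031567	5	34142453	GRIP1	within	2.75E-08	51.56
ALGA0031600	5	34450090	LOC102162670	191680	1.96E-08	52.21
ASGA0025326	5	34580124	LOC102162670	321714	3.17E-08	51.66
ASGA0025359	5	35317229	LOC100037932	within	8.70E-08	50.68
ALGA0031657	5	35416679	IL22	within	4.60E-08	51.18
ALGA0031661	5	35485496	MDM1	within	4.60E-08	51.18
INRA0019196	5	37974847	LOC102158664	6699	9.81E-08	50.45
DRGA0005697	5	39541309	TRHDE	20884	9.93E-08	50.10
DRGA0005727	5	40915894	LOC100524374	253834	1.23E-07	49.63
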