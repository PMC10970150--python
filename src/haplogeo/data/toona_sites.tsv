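population	location	n	longitude	latitude	elevation
XJ	Xianju, Zhejiang	9	119.92	28.45	600
LL	Longlin, Guangxi	10	105.20	24.46	624
SM	Simao, Yunnan	11	100.58	22.46	1317
SC	Suichang, Zhejiang	12	119.25	28.59	510
CB	Chengbu, Hunan	23	111.28	27.14	737
XN	Xinning, Hunan	11	109.44	28.18	650
NP	Nanping, Fujian	9	118.10	26.38	800
JL	Jiulianshan, Jiangxi	18	114.47	24.54	610
DC	Dechang, Sichuan	29	102.32	26.40	1325
XY	Xingyi, Guizhou	15	104.54	25.06	1160
XL	Xilin, Guangxi	24	105.05	24.29	899
WM	Wangmo, Guizhou	30	106.05	25.10	500
YR	Yongren, Yunnan	27	101.32	25.01	1539
BS	Baoshan, Yunnan	11	99.06	25.04	1513
LD	Luodian, Guizhou	14	106.44	25.25	814
TL	Tianlin, Guangxi	26	106.13	24.17	792
CH	Ceheng, Guizhou	22	105.48	24.59	730
HD	Huidong, Sichuan	25	102.09	27.23	1862
JX	Jingxian, Anhui	15	118.24	30.41	366
HS	Huangshan, Anhui	6	118.08	30.16	499
WY	Wuyishan, Fujian	9	117.42	28.18	1200
JG	Jinggangshan, Jiangxi	5	114.17	26.44	400
XE	Xuanen, Hubei	9	109.28	30.17	632
GS	Guanshan, Jiangxi	11	115.26	27.19	337
PW	Puwen, Yunnan	21	101.04	22.23	890
MT	Maotoushan, Jiangxi	9	117.03	27.41	1000
YF	Yunfu, Guangdong	18	111.34	22.46	340
HP	Hupingshan, Hunan	3	111.41	29.01	436
LC	Lechang, Guangdong	15	113.20	25.07	359
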