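population	h_psba_trnh	pi_psba_trnh	h_trnl_trnl	pi_trnl_trnl
XJ	0.5679	0.0015	0.0000	0.0000
LL	0.6600	0.0070	0.8200	0.0031
SM	0.3140	0.0011	0.7934	0.0076
SC	0.5139	0.0017	0.0000	0.0000
CB	0.8809	0.0084	0.3856	0.0008
XN	0.9091	0.0712	0.0000	0.0000
NP	0.8025	0.0070	0.0000	0.0000
JL	0.8765	0.0118	0.0000	0.0000
DC	0.9489	0.0186	0.8252	0.0049
XY	0.5867	0.0046	0.9244	0.0084
XL	0.7396	0.0088	0.9375	0.0073
WM	0.9289	0.0321	0.9489	0.0085
YR	0.9163	0.0087	0.9465	0.0076
BS	0.8926	0.0526	0.9091	0.0066
LD	0.8980	0.0154	0.7653	0.0028
TL	0.9586	0.0257	0.7781	0.0032
CH	0.9504	0.0263	0.9215	0.0043
HD	0.9504	0.0214	0.8928	0.0079
JX	0.3467	0.0161	0.1244	0.0005
HS	0.8333	0.1398	0.2778	0.0019
WY	0.8148	0.0922	0.4938	0.0086
JG	0.8000	0.0768	0.7200	0.0154
XE	0.8889	0.0817	0.4938	0.0041
GS	0.9091	0.1133	0.2975	0.0006
PW	0.8753	0.0144	0.9070	0.0077
MT	0.8889	0.0164	0.0000	0.0000
YF	0.0000	0.0000	0.9321	0.0084
HP	0.4444	0.0027	0.7778	0.0013
LC	0.3378	0.0013	0.2400	0.0027
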