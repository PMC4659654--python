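code	species	1C_bp	ploidy	run_reads
VSA	Vicia sativa	1770000000	2	1050158
VVL	Vicia villosa	2040000000	2	2671672
VLT	Vicia lathyroides	2430000000	2	4812664
VCR	Vicia cracca	5800000000	4	6292470
VTS	Vicia tetrasperma	3050000000	2	7873852
VSP	Vicia sepium	3740000000	2	1897538
VGR	Vicia grandiflora	3780000000	2	3289836
VHR	Vicia hirsuta	3880000000	2	6606736
VER	Vicia ervilia	4060000000	2	4593996
VUN	Vicia unijuga	4370000000	2	7201796
VPN	Vicia pannonica	5730000000	2	2101204
VPF	Vicia pisiformis	6150000000	2	4460146
VNR	Vicia narbonensis	6690000000	2	3588026
VSL	Vicia sylvatica	6980000000	2	4883944
VML	Vicia melanops	8070000000	2	3595696
VPR	Vicia peregrina	8450000000	2	6197134
VFB	Vicia faba	13410000000	2	3192982
LNS	Lens culinaris	4290000000	2	5854630
LAV	Lathyrus vernus	5910000000	2	6632676
LAS	Lathyrus sativus	6520000000	2	3308288
LAL	Lathyrus latifolius	9980000000	2	3091852
PST	Pisum sativum	4360000000	2	4525544
PFL	Pisum fulvum	4690000000	2	5015824
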