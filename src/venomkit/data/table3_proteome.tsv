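rt_min	exp_mw_da	theor_mw_da	names	description	mature	amidated	resolved_name	resolved_mature	resolved_amidated	flags
13.88	1433.54	1433.7	comp17_c0_seq1-4	antimicrobial peptide UyCT3 ndpb precursor	ILSAIWSGIKSLF	true
16.57	4073.81	4073.8	comp849_c0_seq10	alpha-KTx potassium channel blocker precursor	VNIRCSGPKQCFDPCKKETGCSRAKCMNGKCRCNGCR	true
17.10	4054.26	4054.8	comp849_c0_seq4&9;comp1069_c0_seq4	alpha-KTx potassium channel blocker precursor	VDIMCSGPKQCYGPCKKETGCPNAKCMNRRCKCYGCS	true
18.09	4012.20	4012.7	comp1069_c0_seq1;comp849_c0_seq6	alpha-KTx potassium channel blocker precursor	GDIKCSGTRQCWGPCKKQTTCTNSKCMNGKCKCYGCV	true
21.16	4167.08	4167.7	comp1991_c0_seq1-5;comp2100_c0_seq1	alpha-KTx precursor	KYAPTGGCPLSDALCARYCLKHNYGRSGKCDGSTCKCS	false				theor-not-reproducible
22.37	3968.20	3968.6	comp849_c0_seq1;comp849_c0_seq5	alpha-KTx potassium-channel inhibitor kcug2 precursor	GDIKCSSTKECFRPCEEIGGCSNAKCINGKCRCYGCI	true
23.64	4068.00	4068.7	comp10032_c0_seq1;comp11072_c0_seq1	calcium-channel txs2b_liowa	DLPPSDEYGTCVRPRKCKPHLKCSKAQTCVDPKKGW	false
28.41	6576.90	6573.4	comp395_c0_seq1	toxin-like toxin tx707	EENSEEGRTFPLLFSADGRNSLGCWITYSFSYQPTADIDTKIAAQNTLCECMKKGLVPK	false
30.59	7891.57	7892.2	comp12_c0_seq1	la1-like protein 13 precursor	FGESCQAGKHIVPVGQQQIDSSTCTLYKCSNYNRKYALETTSCATLKLKSGCRMVPGAATAPFPNCCPMMMCK	true
31.46	8543.12	8543.9	comp348_c0_seq1;comp299_c0_seq1	toxin-like tx11_opicy	RVVSKKTCKTHTGVILRHGEEWKDPNHCSIYRCTIYDGEAELDGLMCATYQVPRNCKFVRGGGKLYPSCCPTVVCK	false
32.53	7458.64	7458.3	comp330_c0_seq1	alpha-KTx potassium channel blocker precursor	VKCFHNKMCLIPCGMKTGCPEGICVKGRCKCSGC	false	comp330_c0_seq1	EENSEEGRTFPLLFSADGRNSLGCWITYSFSYQPTADIDTKIAAQNTLCECMKKGLVPKGGTTTQPPSG	false	sequence-column-duplicated
33.22	3627.00	3627.5	comp2965_c0_seq1;comp2092_c0_seq1	alpha-KTx potassium channel blocker precursor	VKCFHNKMCLIPCGMKTGCPEGICVKGRCKCSGC	false	comp2092_c0_seq1	IGGCPIDSMCKSYCKNHKYGSEGKCDGTNCKCSL	true	sequence-column-duplicated
33.22	3967.20	3968.6	comp849_c0_seq1;comp849_c0_seq5;comp1069_c0_seq3	alpha-KTx potassium-channel inhibitor kcug2 precursor	GDIKCSSTKECFRPCEEIGGCSNAKCINGKCRCYGCI	true
34.80	4967.22	4967.7	comp6164_c0_seq1;comp6514_c0_seq1	toxin-like toxin tx277	EEKRDSSGRSCSVTGICMKSCARFLHQPANHKKCLPDGVCCTLIY	false
41.14	6464.16	6464.7	comp588_c0_seq1;comp596_c0_seq1	beta-ktx-like peptide	KTTVGQKIKNAAKKVYNKAKDLIGQSEYGCPMVSTFCEQFCKMKKMNGDCDLLKCVCT	false
45.56	6512.47	6511.5	comp1267_c0_seq1	antimicrobial peptide c22 precursor	GIWSWIKKTAKKVWNSDVAKKLKGKALNAAKDFVAEKIGATPAEAGQIPFDEFMNVLYS	false
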