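gene	clade	rgap_locus	rapdb_locus	location	size_aa	signal	gpi	fl_cdna	est	microarray	mpss
OsLTPL1	A	LOC_Os03g26820	Os03g0385400	chr03:15307624..15309776	178	√	√	√	√	√	√
OsXYLP2	A	LOC_Os03g26800	Os03g0385100	chr03:15300737..15301156	139	√	−	−	−	−	√
OsXYLP3	A	LOC_Os07g30590	Os07g0489000	chr07:18102558..18103713	170	√	√	√	√	√	√
OsXYLP4	A	LOC_Os07g43290	Os07g0625800	chr07:25920699..25922871	177	√	√	√	√	√	√
OsXYLP5	A	LOC_Os03g09230	Os03g0192600	chr03:4820699..4822659	214	√	√	√	√	√	√
OsXYLP6	B	LOC_Os03g20760	Os03g0323900	chr03:11751959..11753399	199	√	√	√	√	√	−
OsXYLP7	B	LOC_Os05g41030	Os05g0489200	chr05:24045555..24047844	210	√	√	√	√	√	√
OsXYLP8	B	LOC_Os01g59870	Os01g0814100	chr01:34626255..34628601	187	√	√	√	√	√	√
OsXYLP9	C	LOC_Os07g07790	Os07g0174400	chr07:3910661..3911056	188	√	√	−	√	√	√
OsXYLP10	C	LOC_Os07g07860	Os07g0174900	chr07:3947968..3949371	171	√	√	−	√	√	√
OsXYLP11	C	LOC_Os03g57990	Os03g0794000	chr03:33028009..33029105	189	√	√	−	√	√	√
OsXYLP12	C	LOC_Os07g07870	Os07g0175000	chr07:3950662..3951180	181	√	√	−	−	√	√
OsXYLP13	C	LOC_Os03g57970	Os03g0793800	chr03:33023016..33023942	177	√	√	√	√	√	√
OsXYLP14	C	LOC_Os07g07930	Os07g0175600	chr07:3980211..3981196	170	√	√	√	√	√	√
OsXYLP15	C	LOC_Os04g38840	Os04g0462200	chr04:23093153..2309406	200	√	√	√	√	√	−
OsXYLP16	D	LOC_Os07g09970	Os07g0198300	chr07:5313828..5318057	207	√	√	√	√	√	√
OsXYLP17	D	LOC_Os03g58940	Os03g0804200	chr03:33563702..33566613	195	√	√	√	√	√	√
OsXYLP18	D	LOC_Os03g07100	Os03g0167000	chr03:3626392..3628578	187	√	√	√	√	√	√
OsXYLP19	D	LOC_Os06g47200	Os06g0686400	chr06:28617447..28620310	150	√	√	√	√	√	√
OsXYLP20	D	LOC_Os03g46150	Os03g0664400	chr03:26096042..26096992	243	√	√	√	√	√	√
OsXYLP21	D	LOC_Os08g42040	Os08g0532800	chr08:26554159..26557021	179	√	√	√	√	√	√
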