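isolate	region	source	year
qz274	Near Ping-A highway in Qinghai province	potato	2011
qz275	Near Ping-A highway in Qinghai province	potato	2011
qz279	Near Ping-A highway in Qinghai province	potato	2011
qz280	Near Ping-A highway in Qinghai province	potato	2011
qz504	Huzhu country, Haidong city, Qinghai province	wheat	2011
qz534	Haiyan county, Haibei prefecture, Qinghai province	oat	2011
qz540	Near the Qinghai Lake	oat	2011
qz541	Near the Qinghai Lake	oat	2011
qz543	Huangyuan county, Xining city, Qinghai province	potato	2011
qz544	Huangyuan county, Xining city, Qinghai province	potato	2011
qz545	Huangyuan county, Xining city, Qinghai province	potato	2011
qz546	Jiangxi township, Hainan prefecture, republican county	oat	2011
qz547	Jiangxi township, Hainan prefecture, republican county	oat	2011
qz547-2	Jiangxi township, Hainan prefecture, republican county	oat	2011
qz549	Jiangxi township, Hainan prefecture, republican county	oat	2011
qz568	Huangyuan county, Xining city, Qinghai province	potato	2011
qz569	Huangyuan county, Xining city, Qinghai province	potato	2011
qz594	Huzhu country, Haidong city, Qinghai province	potato	2011
qz695	Dahua town, Huangyuan county, Xining city, Qinghai province	potato	2011
qz733	Changning town, Datong county, Xining city, Qinghai province	wheat	2011
qz768	Haiyan county, Haibei prefecture, Qinghai province	potato	2011
qz769	Haiyan county, Haibei prefecture, Qinghai province	potato	2011
qz770	Haiyan county, Haibei prefecture, Qinghai province	potato	2011
qz771	Haiyan county, Haibei prefecture, Qinghai province	potato	2011
qz772	Haiyan county, Haibei prefecture, Qinghai province	potato	2011
cw17	Guoluo Tibetan autonomous prefecture, Qinghai province	Qula	2008
cw18	Guoluo Tibetan autonomous prefecture, Qinghai province	Qula	2008
cw19	Guoluo Tibetan autonomous prefecture, Qinghai province	Qula	2008
cw20	Guoluo Tibetan autonomous prefecture, Qinghai province	Qula	2008
cw21	Gangcha county, Haibei prefecture, Qinghai province	Qula	2008
cw22	Gangcha county, Haibei prefecture, Qinghai province	Qula	2008
cw23	Huangnan Tibetan autonomous prefecture of Qinghai province	Qula	2008
cw25	Huangnan Tibetan autonomous prefecture of Qinghai province	Qula	2008
cw26	Huangnan Tibetan autonomous prefecture of Qinghai province	Qula	2008
cw27	Huangnan Tibetan autonomous prefecture of Qinghai province	Qula	2008
cw28	Gannan Tibetan autonomous prefecture, Gansu province	Qula	2008
cw29	Gannan Tibetan autonomous prefecture, Gansu province	Qula	2008
cw31	Yushu Tibetan autonomous prefecture of Qinghai province	Qula	2008
cw32	Yushu Tibetan autonomous prefecture of Qinghai province	Qula	2008
cw33	Yushu Tibetan autonomous prefecture of Qinghai province	Qula	2008
cw34	Yushu Tibetan autonomous prefecture of Qinghai province	Qula	2008
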