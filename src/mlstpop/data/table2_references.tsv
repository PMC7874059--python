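isolate	subspecies	year	source
JCM6124	Leuconostoc mesenteroides subsp. mesenteroides	1980	fermenting olives
JCM16943	Leuconostoc mesenteroides subsp. cremoris	1983	infant
CGMCC1.2141	Leuconostoc mesenteroides subsp. dextranicum	1983	infant
CGMCC1.2138	Leuconostoc mesenteroides subsp. suionicum	1983	fermenting olives
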