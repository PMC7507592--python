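year,province,region,population_10k,area_km2,institutions,technical_personnel,beds,equipment
2013,National total,,136072,,31155,608560,214870,481148
2014,National total,,136782,,35029,631558,223033,530587
2015,National total,,137462,,31927,639189,236342,572371
2016,National total,,138271,,24866,646425,247228,618857
2017,National total,,139008,,19896,661616,262570,686572
2018,National total,,139538,,18033,678258,274394,742759
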