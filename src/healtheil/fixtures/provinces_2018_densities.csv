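year,province,region,institutions_per_km2,institutions_per_10k,technical_personnel_per_km2,technical_personnel_per_10k,beds_per_km2,beds_per_10k
2018,Inner Mongolia,western,0.000,0.193,0.013,6.058,0.004,1.712
2018,Guangxi,western,0.005,0.255,0.153,7.333,0.061,2.939
2018,Chongqing,western,0.002,0.049,0.133,3.534,0.055,1.464
2018,Sichuan,western,0.001,0.084,0.074,4.297,0.027,1.539
2018,Yunnan,western,0.001,0.108,0.062,4.894,0.021,1.655
2018,Tibet,western,0.000,0.422,0.001,4.285,0.000,1.087
2018,Gansu,western,0.003,0.529,0.031,5.273,0.011,1.905
2018,Shaanxi,western,0.003,0.159,0.115,6.144,0.042,2.239
2018,Guizhou,western,0.002,0.095,0.100,4.902,0.048,2.342
2018,Ningxia,western,0.001,0.128,0.063,6.077,0.019,1.820
2018,Qinghai,western,0.000,0.295,0.004,4.839,0.001,0.839
2018,Xinjiang,western,0.000,0.280,0.007,4.799,0.002,1.195
2018,Jilin,middle,0.002,0.150,0.062,4.269,0.015,1.069
2018,Anhui,middle,0.004,0.096,0.123,2.709,0.050,1.114
2018,Heilongjiang,middle,0.002,0.195,0.038,4.609,0.018,2.111
2018,Henan,middle,0.010,0.165,0.302,5.252,0.154,2.678
2018,Hubei,middle,0.003,0.085,0.179,5.637,0.092,2.892
2018,Hunan,middle,0.004,0.123,0.179,5.499,0.090,2.764
2018,Jiangxi,middle,0.004,0.159,0.150,5.381,0.084,3.017
2018,Shanxi,middle,0.003,0.121,0.120,5.032,0.033,1.379
2018,Tianjin,eastern,0.008,0.062,0.385,2.785,0.063,0.454
2018,Beijing,eastern,0.007,0.051,0.715,5.577,0.146,1.140
2018,Guangdong,eastern,0.006,0.093,0.363,5.759,0.164,2.597
2018,Liaoning,eastern,0.005,0.154,0.093,3.104,0.025,0.824
2018,Hebei,eastern,0.004,0.091,0.159,3.956,0.072,1.789
2018,Shanghai,eastern,0.017,0.045,1.403,3.646,0.212,0.552
2018,Jiangsu,eastern,0.008,0.100,0.251,3.200,0.073,0.925
2018,Zhejiang,eastern,0.004,0.069,0.257,4.572,0.092,1.628
2018,Shandong,eastern,0.007,0.108,0.328,5.017,0.168,2.575
2018,Hainan,eastern,0.004,0.127,0.173,6.301,0.051,1.870
2018,Fujian,eastern,0.004,0.114,0.139,4.267,0.071,2.172
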