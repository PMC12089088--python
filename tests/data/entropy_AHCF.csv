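index,k1n2,k1n3,k1n4,k1n5,k2n2,k2n3,k2n4,k2n5,k3n2,k3n3,k3n4,k3n5
M1,10.1830,11.6202,12.5802,13.3006,10.2193,11.6560,12.6158,13.3362,10.1716,11.6105,12.5712,13.2921
M2,10.0142,11.4519,12.4122,13.1329,10.1664,11.6038,12.5640,13.2845,10.0201,11.4661,12.4301,13.1528
F,9.9991,11.4353,12.3951,13.1154,10.1615,11.5987,12.5588,13.2793,10.0880,11.5308,12.4933,13.2152
S,10.1792,11.6162,12.5762,13.2967,10.2185,11.6552,12.6150,13.3353,10.1789,11.6175,12.5782,13.2990
GA,10.2356,11.6720,12.6317,13.3519,10.2360,11.6724,12.6320,13.3523,10.2334,11.6699,12.6296,13.3499
ReZ1,10.2048,11.6422,12.6024,13.3229,10.2238,11.6606,12.6204,13.3408,10.0918,11.5290,12.4891,13.2096
ReZ2,10.1885,11.6258,12.5859,13.3063,10.2206,11.6573,12.6172,13.3375,10.1437,11.5835,12.5448,13.2659
H,10.1972,11.6348,12.5951,13.3157,10.2222,11.6591,12.6189,13.3393,10.1054,11.5438,12.5045,13.2253
HZ,10.0083,11.4452,12.4053,13.1258,10.1642,11.6015,12.5616,13.2821,10.0607,11.5047,12.4678,13.1900
BM,10.1300,11.5676,12.5279,13.2484,10.1955,11.6326,12.5925,13.3130,10.1012,11.5431,12.5053,13.2269
TM,10.0056,11.4422,12.4022,13.1226,10.1633,11.6006,12.5607,13.2812,10.0711,11.5146,12.4775,13.1995
GBM,10.2287,11.6653,12.6251,13.3453,10.2318,11.6683,12.6280,13.3483,10.2114,11.6483,12.6082,13.3286
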