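index,k1n2,k1n3,k1n4,k1n5,k2n2,k2n3,k2n4,k2n5,k3n2,k3n3,k3n4,k3n5
M1,9.1164,10.1830,10.9586,11.5688,9.1529,10.2193,10.9947,11.6047,9.1031,10.1716,10.9482,11.5590
M2,8.9473,10.0142,10.7901,11.4005,9.0995,10.1664,10.9422,11.5524,8.9443,10.0201,10.8008,11.4143
F,8.9337,9.9991,10.7741,11.3840,9.0947,10.1615,10.9371,11.5474,9.0154,10.0880,10.8669,11.4791
S,9.1126,10.1792,10.9548,11.5649,9.1521,10.2185,10.9939,11.6039,9.1106,10.1789,10.9554,11.5661
GA,9.1695,10.2356,11.0108,11.6207,9.1699,10.2360,11.0112,11.6211,9.1673,10.2334,11.0087,11.6186
ReZ1,9.1376,10.2048,10.9806,11.5909,9.1574,10.2238,10.9992,11.6093,9.0253,10.0918,10.8674,11.4776
ReZ2,9.1216,10.1885,10.9642,11.5744,9.1542,10.2206,10.9960,11.6060,9.0742,10.1437,10.9209,11.5320
H,9.1298,10.1972,10.9731,11.5835,9.1558,10.2222,10.9977,11.6078,9.0376,10.1054,10.8818,11.4924
HZ,8.9422,10.0083,10.7838,11.3939,9.0973,10.1642,10.9399,11.5501,8.9869,10.0607,10.8403,11.4530
BM,9.0630,10.1300,10.9059,11.5162,9.1288,10.1955,10.9711,11.5812,9.0296,10.1012,10.8796,11.4915
TM,8.9397,10.0056,10.7809,11.3909,9.0965,10.1633,10.9390,11.5492,8.9977,10.0711,10.8504,11.4629
GBM,9.1624,10.2287,11.0040,11.6140,9.1656,10.2318,11.0071,11.6170,9.1448,10.2114,10.9869,11.5970
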