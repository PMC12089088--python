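index,k1n2,k1n3,k1n4,k1n5,k2n2,k2n3,k2n4,k2n5,k3n2,k3n3,k3n4,k3n5
M1,9.3772,10.5436,11.3720,12.0148,9.4136,10.5797,11.4078,12.0505,9.3651,10.5332,11.3624,12.0057
M2,9.2082,10.3750,11.2037,11.8468,9.3605,10.5271,11.3556,11.9986,9.2105,10.3858,11.2186,11.8641
F,9.1938,10.3591,11.1871,11.8297,9.3556,10.5221,11.3505,11.9934,9.2797,10.4518,11.2830,11.9276
S,9.3734,10.5397,11.3680,12.0109,9.4128,10.5788,11.4070,12.0497,9.3724,10.5404,11.3695,12.0127
GA,9.4300,10.5958,11.4237,12.0663,9.4304,10.5961,11.4241,12.0667,9.4278,10.5937,11.4217,12.0643
ReZ1,9.3988,10.5656,11.3941,12.0370,9.4181,10.5842,11.4124,12.0551,9.2860,10.4524,11.2808,11.9237
ReZ2,9.3825,10.5491,11.3776,12.0205,9.4149,10.5810,11.4091,12.0518,9.3367,10.5058,11.3356,11.9792
H,9.3911,10.5581,11.3867,12.0297,9.4165,10.5827,11.4108,12.0536,9.2991,10.4667,11.2957,11.9390
HZ,9.2027,10.3687,11.1970,11.8399,9.3583,10.5248,11.3533,11.9962,9.2519,10.4253,11.2571,11.9020
BM,9.3240,10.4908,11.3194,11.9624,9.3896,10.5560,11.3843,12.0272,9.2934,10.4646,11.2953,11.9396
TM,9.2001,10.3658,11.1940,11.8368,9.3574,10.5240,11.3524,11.9953,9.2625,10.4353,11.2669,11.9117
GBM,9.4230,10.5890,11.4171,12.0597,9.4262,10.5920,11.4201,12.0627,9.4056,10.5718,11.4001,12.0428
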