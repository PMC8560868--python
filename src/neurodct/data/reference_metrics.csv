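method_id,rci,cen_ad,cen_nc,cen_pd,iba_ad,iba_nc,iba_pd,gm_ad,gm_nc,gm_pd,mcc_ad,mcc_nc,mcc_pd
1,0.916,0,0.093,0.091,1,0.958,0.921,1,0.98,0.974,1,0.953,0.954
2,0.9046,0,0.1071,0.1022,1,0.9171,0.9404,1,0.9708,0.9742,1,0.9445,0.9462
3,0.9046,0,0.1071,0.1022,1,0.9171,0.9405,1,0.9708,0.9742,1,0.9445,0.9462
4,0.8976,0,0.1124,0.1115,1,0.9576,0.8829,1,0.9738,0.964,1,0.9378,0.9381
5,0.8862,0,0.1255,0.1236,1,0.9372,0.8831,1,0.9685,0.9615,1,0.9296,0.9304
6,0.885,0,0.129,0.123,1,0.897,0.921,1,0.963,0.966,1,0.93,0.93
7,0.8848,0,0.1281,0.1243,1,0.9171,0.9021,1,0.9657,0.964,1,0.929,0.9304
8,0.885,0,0.128,0.124,1,0.917,0.902,1,0.965,0.964,1,0.929,0.93
9,0.8848,0,0.1282,0.1243,1,0.9171,0.9021,1,0.9657,0.964,1,0.929,0.9304
10,0.8675,0,0.1458,0.1436,1,0.9169,0.8646,1,0.9606,0.9537,1,0.914,0.915
11,0.862,0,0.149,0.15,1,0.937,0.828,1,0.96,0.946,1,0.908,0.907
12,0.858,0,0.1568,0.1533,1,0.897,0.8647,1,0.9552,0.9511,1,0.9057,0.9071
13,0.858,0,0.156,0.153,1,0.897,0.864,1,0.955,0.951,1,0.905,0.907
14,0.8491,0,0.167,0.1622,1,0.8773,0.8647,1,0.9498,0.9485,1,0.8975,0.8995
15,0.8412,0,0.1749,0.1712,1,0.8773,0.8463,1,0.9473,0.9433,1,0.8899,0.8916
16,0.8332,0,0.1863,0.1759,1,0.8195,0.883,1,0.936,0.9457,1,0.8806,0.8854
17,0.7519,0.279,0.265,0,0.729,0.7481,1,0.8898,0.8945,1,0.7814,0.79,1
18,0.7464,0.2859,0.2702,0,0.7116,0.7483,1,0.8842,0.892,1,0.773,0.7832,1
19,0.7308,0.3054,0.2838,0,0.6605,0.7478,1,0.8673,0.8845,1,0.7477,0.7628,1
20,0.6266,0.3272,0.3924,0.0983,0.6279,0.61,0.998,0.8528,0.8333,0.9778,0.7198,0.678,0.9361
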