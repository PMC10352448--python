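table,m,For_Nc50,Int_Nc50,Back_Nc50,For_Nc500,Int_Nc500,Back_Nc500
same,0.1,47.2960,47.5232,47.7504,56.4109,56.6337,56.8566
same,0.2,45.0331,45.2609,45.4888,64.3622,64.5805,64.7988
same,0.3,42.7467,42.9755,43.2043,74.2336,74.4468,74.6600
same,0.4,40.4368,40.6667,40.8966,86.5645,86.7714,86.9783
same,0.5,38.1032,38.3342,38.5652,101.9387,102.1379,102.3371
same,0.6,35.7455,35.9777,36.2098,120.7432,120.9329,121.1227
same,0.7,33.3633,33.5967,33.8300,142.4849,142.6637,142.8426
same,0.8,30.9564,31.1909,31.4254,164.3497,164.5176,164.6854
same,0.9,28.5242,28.7599,28.9956,179.5012,179.6615,179.8217
same,1.0,26.0664,26.3033,26.5403,178.4566,178.6174,178.7781
different,0.1,4.6878,4.9355,5.1833,5.6902,5.9375,6.1847
different,0.2,8.9166,9.1622,9.4078,13.1853,13.4288,13.6723
different,0.3,12.6738,12.9175,13.1612,23.1186,23.3572,23.5957
different,0.4,15.9668,16.2089,16.4509,36.3781,36.6100,36.8419
different,0.5,18.8007,19.0413,19.2820,54.0715,54.2945,54.5176
different,0.6,21.1778,21.4172,21.6567,77.2921,77.5035,77.7149
different,0.7,23.0977,23.3362,23.5746,106.2835,106.4804,106.6774
different,0.8,24.5571,24.7948,25.0326,138.5156,138.6964,138.8772
different,0.9,25.5498,25.7870,26.0242,166.3374,166.5042,166.6710
different,1.0,26.0664,26.3033,26.5403,178.4566,178.6174,178.7781
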