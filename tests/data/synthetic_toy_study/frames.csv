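retina_id,species,eye_side,x_mm,y_mm,frame_side_um,frames_per_site,count
sp01_r1,sp01,right,2.5528,-2.3142,50.0,25,31
sp01_r1,sp01,right,0.8594,0.7607,50.0,25,151
sp01_r1,sp01,right,1.0165,-1.8328,50.0,25,98
sp01_r1,sp01,right,1.7297,2.1067,50.0,25,79
sp01_r1,sp01,right,0.0262,-0.9265,50.0,25,188
sp01_r1,sp01,right,-2.5277,2.1117,50.0,25,64
sp01_r1,sp01,right,-1.6647,-0.8111,50.0,25,164
sp01_r1,sp01,right,0.7005,3.2685,50.0,25,51
sp01_r1,sp01,right,-1.9436,-1.0977,50.0,25,131
sp01_r1,sp01,right,-2.6576,2.6282,50.0,25,46
sp01_r1,sp01,right,2.8305,1.7107,50.0,25,58
sp01_r1,sp01,right,3.669,-0.2259,50.0,25,47
sp01_r1,sp01,right,-0.2569,-3.6182,50.0,25,46
sp01_r1,sp01,right,1.7238,-2.9984,50.0,25,47
sp01_r1,sp01,right,-1.0151,3.1729,50.0,25,61
sp01_r1,sp01,right,-1.2766,2.632,50.0,25,100
sp01_r1,sp01,right,0.8427,-3.658,50.0,25,39
sp01_r1,sp01,right,-1.0703,-0.964,50.0,25,160
sp01_r1,sp01,right,0.4539,3.3751,50.0,25,62
sp01_r1,sp01,right,3.6897,0.0547,50.0,25,47
sp01_r1,sp01,right,-1.9633,0.5645,50.0,25,151
sp01_r1,sp01,right,2.2672,3.1484,50.0,25,43
sp01_r1,sp01,right,2.6339,-2.3238,50.0,25,46
sp01_r1,sp01,right,1.8133,1.9626,50.0,25,93
sp01_r1,sp01,right,3.5773,1.1321,50.0,25,44
sp01_r1,sp01,right,0.4134,-3.5947,50.0,25,40
sp01_r1,sp01,right,2.7478,-1.7992,50.0,25,42
sp01_r1,sp01,right,1.3521,-2.3253,50.0,25,80
sp01_r1,sp01,right,2.4654,1.3712,50.0,25,66
sp01_r1,sp01,right,-1.0235,-2.4909,50.0,25,73
sp01_r1,sp01,right,-0.1055,-2.023,50.0,25,117
sp01_r1,sp01,right,3.0361,-0.0191,50.0,25,60
sp01_r1,sp01,right,-1.4169,3.5419,50.0,25,38
sp01_r1,sp01,right,-0.364,3.9135,50.0,25,45
sp01_r1,sp01,right,-3.8496,0.9522,50.0,25,42
sp01_r1,sp01,right,2.4619,1.2412,50.0,25,83
sp01_r1,sp01,right,1.2749,-3.1902,50.0,25,54
sp01_r1,sp01,right,-0.9733,2.9138,50.0,25,88
sp01_r1,sp01,right,-1.2443,-1.5713,50.0,25,165
sp01_r1,sp01,right,-2.1633,1.1855,50.0,25,121
sp02_r1,sp02,right,-2.5759,-2.3169,50.0,25,66
sp02_r1,sp02,right,-2.3061,-1.4105,50.0,25,99
sp02_r1,sp02,right,0.8926,3.5757,50.0,25,36
sp02_r1,sp02,right,3.055,1.1187,50.0,25,73
sp02_r1,sp02,right,-0.4161,-2.2029,50.0,25,131
sp02_r1,sp02,right,2.7301,2.7845,50.0,25,37
sp02_r1,sp02,right,3.0298,2.3882,50.0,25,26
sp02_r1,sp02,right,0.2831,1.2067,50.0,25,165
sp02_r1,sp02,right,2.4425,0.4925,50.0,25,83
sp02_r1,sp02,right,-1.4875,-1.7241,50.0,25,120
sp02_r1,sp02,right,0.3581,3.6766,50.0,25,31
sp02_r1,sp02,right,1.8148,3.2364,50.0,25,45
sp02_r1,sp02,right,3.0904,-1.7609,50.0,25,37
sp02_r1,sp02,right,0.6451,0.2449,50.0,25,186
sp02_r1,sp02,right,-1.7909,1.3133,50.0,25,153
sp02_r1,sp02,right,1.3112,2.9831,50.0,25,66
sp02_r1,sp02,right,-2.324,2.019,50.0,25,82
sp02_r1,sp02,right,2.3126,-1.7398,50.0,25,84
sp02_r1,sp02,right,1.9326,-2.1936,50.0,25,73
sp02_r1,sp02,right,1.8945,-3.4682,50.0,25,34
sp02_r1,sp02,right,-0.0722,1.8592,50.0,25,121
sp02_r1,sp02,right,2.4176,2.7141,50.0,25,33
sp02_r1,sp02,right,-2.048,-2.4125,50.0,25,71
sp02_r1,sp02,right,-2.906,0.866,50.0,25,90
sp02_r1,sp02,right,2.2444,-2.2874,50.0,25,55
sp02_r1,sp02,right,1.3809,-0.3956,50.0,25,144
sp02_r1,sp02,right,2.5385,0.7443,50.0,25,67
sp02_r1,sp02,right,3.598,-0.1009,50.0,25,52
sp02_r1,sp02,right,-0.8943,-0.8807,50.0,25,218
sp02_r1,sp02,right,0.8913,1.016,50.0,25,141
sp02_r1,sp02,right,1.1346,2.4523,50.0,25,83
sp02_r1,sp02,right,-0.5095,-1.1864,50.0,25,160
sp02_r1,sp02,right,-0.8106,-1.0698,50.0,25,162
sp02_r1,sp02,right,-0.9452,-1.096,50.0,25,174
sp02_r1,sp02,right,0.0817,0.3624,50.0,25,208
sp02_r1,sp02,right,1.1247,-2.6101,50.0,25,61
sp02_r1,sp02,right,-1.9777,3.0745,50.0,25,59
sp02_r1,sp02,right,-2.3089,1.6502,50.0,25,91
sp02_r1,sp02,right,-2.5295,2.8492,50.0,25,44
sp02_r1,sp02,right,2.0174,3.0932,50.0,25,37
sp03_r1,sp03,right,-2.1032,-1.0375,50.0,25,160
sp03_r1,sp03,right,-1.7751,0.9199,50.0,25,188
sp03_r1,sp03,right,-2.4742,0.3637,50.0,25,171
sp03_r1,sp03,right,-3.6011,0.6351,50.0,25,78
sp03_r1,sp03,right,2.4888,-2.7584,50.0,25,56
sp03_r1,sp03,right,1.3071,0.572,50.0,25,191
sp03_r1,sp03,right,0.1394,-3.8783,50.0,25,65
sp03_r1,sp03,right,0.4827,-3.5587,50.0,25,79
sp03_r1,sp03,right,2.3448,-1.2087,50.0,25,137
sp03_r1,sp03,right,1.4319,3.4402,50.0,25,72
sp03_r1,sp03,right,0.758,-0.9637,50.0,25,206
sp03_r1,sp03,right,-2.3951,0.0439,50.0,25,138
sp03_r1,sp03,right,1.2642,-1.1331,50.0,25,171
sp03_r1,sp03,right,-1.0576,0.587,50.0,25,203
sp03_r1,sp03,right,0.022,-1.6896,50.0,25,159
sp03_r1,sp03,right,-0.4119,-0.8975,50.0,25,207
sp03_r1,sp03,right,3.2614,-1.5907,50.0,25,63
sp03_r1,sp03,right,-2.9194,1.1503,50.0,25,122
sp03_r1,sp03,right,-1.2786,3.0245,50.0,25,104
sp03_r1,sp03,right,-0.5858,-0.5124,50.0,25,236
sp03_r1,sp03,right,-3.8436,0.8743,50.0,25,70
sp03_r1,sp03,right,-0.2183,1.2367,50.0,25,226
sp03_r1,sp03,right,1.906,-3.4527,50.0,25,47
sp03_r1,sp03,right,1.1242,3.756,50.0,25,45
sp03_r1,sp03,right,0.8605,2.5059,50.0,25,150
sp03_r1,sp03,right,1.0894,3.2762,50.0,25,78
sp03_r1,sp03,right,-2.0318,0.1696,50.0,25,182
sp03_r1,sp03,right,0.6329,3.3386,50.0,25,84
sp03_r1,sp03,right,-2.1916,-2.0501,50.0,25,124
sp03_r1,sp03,right,3.6229,-0.9445,50.0,25,65
sp03_r1,sp03,right,-0.5585,-2.4787,50.0,25,153
sp03_r1,sp03,right,-2.6211,-2.0973,50.0,25,107
sp03_r1,sp03,right,-0.4978,2.6717,50.0,25,145
sp03_r1,sp03,right,-3.0839,-0.2472,50.0,25,159
sp03_r1,sp03,right,-3.2906,0.5434,50.0,25,123
sp03_r1,sp03,right,0.5947,1.0642,50.0,25,198
sp03_r1,sp03,right,-2.3755,-0.9162,50.0,25,159
sp03_r1,sp03,right,0.9336,2.1404,50.0,25,172
sp03_r1,sp03,right,2.8882,0.6809,50.0,25,78
sp03_r1,sp03,right,3.6067,-0.942,50.0,25,70
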