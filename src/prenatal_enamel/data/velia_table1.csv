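id,arch,nl_present,pcft_direct_days,pcft_regression_days,deviation_days,dsr_mean_um_day,dsr_sd,dsr_n,cuspal_middle_eer_um_day,eer_mean_um_day,eer_sd,eer_n
T98,upper,true,179,145,34,3.81,0.20,3,54.0,30.77,21.25,3
T142,lower,false,105,97,8,4.28,0.24,3,58.0,42.70,21.64,2
T155,upper,false,145,127,18,4.18,0.60,4,37.7,28.33,8.81,3
T168,upper,false,120,120,0,4.75,0.37,3,55.4,35.53,17.64,3
T197,upper,true,120,114,6,4.25,0.41,3,51.9,38.37,12.20,3
T221,lower,false,76,67,9,4.20,0.29,3,53.8,37.43,14.59,3
T229,upper,true,138,134,4,4.57,0.29,3,54.5,33.10,18.65,3
T237,lower,false,102,93,9,4.14,0.33,4,54.3,41.90,10.92,3
T243,upper,true,100,111,-11,5.18,0.17,4,84.3,46.65,25.77,4
T252,upper,false,164,133,31,3.63,0.53,8,59.1,31.34,14.37,7
T301,lower,false,109,104,5,4.37,0.33,5,41.1,51.08,6.66,4
T312,upper,false,133,130,3,4.54,0.29,6,63.3,42.28,12.21,6
T330,upper,false,108,118,-10,5.04,0.29,5,55.2,41.50,14.77,4
T344,upper,false,114,130,-16,5.31,0.40,5,59.3,45.98,14.17,4
T349,lower,false,135,146,-11,5.01,0.33,5,67.4,41.17,22.82,3
T399,lower,true,114,121,-7,4.95,0.56,4,39.7,35.68,5.56,4
T422,upper,false,73,82,-9,5.22,0.49,3,59.6,48.35,15.91,2
T438,upper,false,111,123,-12,4.98,0.63,5,65.4,51.63,11.24,4
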