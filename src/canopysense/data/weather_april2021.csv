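date,t_min,t_max,rainfall,wind_dir,wind_speed_max,wind_time_max,t_9am,rh_9am,wind_dir_9am,ws_9am,mslp_9am,t_3pm,rh_3pm,wind_dir_3pm,ws_3pm,mslp_3pm
2021-04-19,12,20.6,0,NW,30,13:27,15.3,64,N,9,1018.4,18.9,47,NNW,15,1014.1
2021-04-21,7.1,14.9,10.4,N,19,23:00,10,65,NW,2,1019.2,14.2,48,S,7,1015.4
2021-04-22,9.9,17,0,WSW,30,16:15,13.4,62,NNW,13,1013.3,16.8,46,WNW,9,1012
2021-04-29,8.2,18.4,0,SSW,17,13:44,12,83,,Calm,1025.1,17.5,66,SSW,9,1022.9
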