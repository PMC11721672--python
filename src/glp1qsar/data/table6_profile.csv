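id,ec50_nM,censored,emax_pct,group,parent_id
RXL-3000,0.1,0,109.2,ala_scan,RXL-3000
RXL-3001,21.9,0,107.5,ala_scan,RXL-3000
RXL-3002,0.2,0,102.5,ala_scan,RXL-3000
RXL-3003,7.9,0,108.2,ala_scan,RXL-3000
RXL-3037,210.0,0,73.8,ala_scan,RXL-3000
RXL-3004,7.7,0,108.2,ala_scan,RXL-3000
RXL-3038,,1,37.4,ala_scan,RXL-3000
RXL-3005,47.5,0,102.4,ala_scan,RXL-3000
RXL-3006,8.5,0,120.1,ala_scan,RXL-3000
RXL-3007,14.0,0,131.6,ala_scan,RXL-3000
RXL-3008,,1,43.6,ala_scan,RXL-3000
RXL-3009,,1,43.2,ala_scan,RXL-3000
RXL-101,0.01,0,116.7,aib_scan,RXL-101
RXL-3030,1.3,0,111.6,aib_scan,RXL-101
RXL-3031,4.0,0,121.3,aib_scan,RXL-101
RXL-3032,14.2,0,117.7,aib_scan,RXL-101
RXL-3033,6.9,0,119.9,aib_scan,RXL-101
RXL-3028,161.0,0,76.1,aib_scan,RXL-101
RXL-3034,80.2,0,105.7,aib_scan,RXL-101
RXL-3035,111.0,0,79.1,aib_scan,RXL-101
RXL-3036,67.5,0,96.7,aib_scan,RXL-101
RXL-3051,,1,26.8,aib_scan,RXL-101
RXL-3052,7.4,0,112.3,aib_scan,RXL-101
RXL-100,0.5,0,109.6,phe6_mod,RXL-3000
RXL-3010,3.9,0,120.6,phe6_mod,RXL-3000
RXL-3011,0.9,0,91.3,phe6_mod,RXL-3000
RXL-3012,13.9,0,99.3,phe6_mod,RXL-3000
RXL-3013,2.1,0,98.6,phe6_mod,RXL-3000
RXL-3014,1.1,0,104.5,phe6_mod,RXL-3000
RXL-3015,7.7,0,101.0,phe6_mod,RXL-3000
RXL-3016,13.9,0,108.9,phe6_mod,RXL-3000
RXL-3017,7.2,0,113.1,phe6_mod,RXL-3000
RXL-3018,0.3,0,102.5,phe6_mod,RXL-3000
RXL-3019,16.0,0,109.5,phe6_mod,RXL-3000
RXL-3020,0.02,0,107.9,phe6_mod,RXL-3000
RXL-3021,3.0,0,100.2,phe6_mod,RXL-3000
RXL-3022,23.2,0,101.4,phe6_mod,RXL-3000
RXL-3023,13.8,0,106.3,phe6_mod,RXL-3000
RXL-3024,10.8,0,102.3,phe6_mod,RXL-3000
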