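id,pos1,pos2,pos3,pos4,pos5,pos6,pos7,pos8,pos9,pos10,pos11,ec50_nM,censored,emax_pct,pec50,series,in_training_31
RXL-100,His,Aib,Glu,Gly,Thr,Phe,Thr,Ser,Asp,Bip,Bip,0.5,0,109.6,,parent,1
RXL-3000,His,Aib,Glu,Gly,Thr,Phe(2-F),Thr,Ser,Asp,Bip,Bip,0.1,0,109.2,9.92,parent,1
RXL-101,His,Aib,Glu,Gly,Thr,aMe-Phe(2-F),Thr,Ser,Asp,Bip,Bip,0.01,0,116.7,10.89,parent,1
RXL-3010,His,Aib,Glu,Gly,Thr,Phe(2-Br),Thr,Ser,Asp,Bip,Bip,3.85,0,120.6,,phe6_mod,1
RXL-3011,His,Aib,Glu,Gly,Thr,Phe(2-Cl),Thr,Ser,Asp,Bip,Bip,0.9,0,91.3,,phe6_mod,1
RXL-3012,His,Aib,Glu,Gly,Thr,Phe(2-CF3),Thr,Ser,Asp,Bip,Bip,13.9,0,99.3,,phe6_mod,1
RXL-3013,His,Aib,Glu,Gly,Thr,Phe(2-CH3),Thr,Ser,Asp,Bip,Bip,2.1,0,98.6,,phe6_mod,1
RXL-3014,His,Aib,Glu,Gly,Thr,Phe(2-NO2),Thr,Ser,Asp,Bip,Bip,1.1,0,104.5,,phe6_mod,1
RXL-3015,His,Aib,Glu,Gly,Thr,Phe(2-CN),Thr,Ser,Asp,Bip,Bip,7.7,0,101.0,,phe6_mod,1
RXL-3016,His,Aib,Glu,Gly,Thr,Phe(3-CF3),Thr,Ser,Asp,Bip,Bip,13.9,0,108.9,,phe6_mod,1
RXL-3039,His,Aib,Glu,Gly,Thr,"Phe(2,6-F)",Thr,Ser,Asp,Bip,Bip,0.16,0,,,phe6_mod,0
RXL-3017,His,Aib,Glu,Gly,Thr,"Phe(3,4,5-F)",Thr,Ser,Asp,Bip,Bip,7.2,0,113.1,,phe6_mod,0
RXL-3018,His,Aib,Glu,Gly,Thr,"Phe(2,3,4,5,6-F)",Thr,Ser,Asp,Bip,Bip,0.3,0,102.5,,phe6_mod,0
RXL-3019,His,Aib,Glu,Gly,Thr,Hph,Thr,Ser,Asp,Bip,Bip,16.0,0,109.5,,phe6_mod,0
RXL-3020,His,Aib,Glu,Gly,Thr,aMe-Phe,Thr,Ser,Asp,Bip,Bip,0.02,0,107.9,,phe6_mod,0
RXL-3021,His,Aib,Glu,Gly,Thr,Tyr,Thr,Ser,Asp,Bip,Bip,3.0,0,100.2,,phe6_mod,0
RXL-3022,His,Aib,Glu,Gly,Thr,D-Phe,Thr,Ser,Asp,Bip,Bip,23.2,0,101.4,,phe6_mod,0
RXL-3023,His,Aib,Glu,Gly,Thr,Trp,Thr,Ser,Asp,Bip,Bip,13.8,0,106.3,,phe6_mod,0
RXL-3024,His,Aib,Glu,Gly,Thr,Bip,Thr,Ser,Asp,Bip,Bip,10.8,0,102.3,,phe6_mod,0
RXL-3001,Ala,Aib,Glu,Gly,Thr,Phe(2-F),Thr,Ser,Asp,Bip,Bip,21.9,0,107.5,7.86,ala_scan,1
RXL-3002,His,Ala,Glu,Gly,Thr,Phe(2-F),Thr,Ser,Asp,Bip,Bip,0.2,0,102.5,9.92,ala_scan,1
RXL-3003,His,Aib,Ala,Gly,Thr,Phe(2-F),Thr,Ser,Asp,Bip,Bip,7.9,0,108.2,8.47,ala_scan,1
RXL-3037,His,Aib,Glu,Ala,Thr,Phe(2-F),Thr,Ser,Asp,Bip,Bip,210.0,0,73.8,6.46,ala_scan,1
RXL-3004,His,Aib,Glu,Gly,Ala,Phe(2-F),Thr,Ser,Asp,Bip,Bip,7.7,0,108.2,8.16,ala_scan,1
RXL-3038,His,Aib,Glu,Gly,Thr,Ala,Thr,Ser,Asp,Bip,Bip,,1,37.4,5.55,ala_scan,1
RXL-3005,His,Aib,Glu,Gly,Thr,Phe(2-F),Ala,Ser,Asp,Bip,Bip,47.5,0,102.4,7.67,ala_scan,1
RXL-3006,His,Aib,Glu,Gly,Thr,Phe(2-F),Thr,Ala,Asp,Bip,Bip,8.5,0,120.1,8.72,ala_scan,1
RXL-3007,His,Aib,Glu,Gly,Thr,Phe(2-F),Thr,Ser,Ala,Bip,Bip,14.0,0,131.6,8.32,ala_scan,1
RXL-3008,His,Aib,Glu,Gly,Thr,Phe(2-F),Thr,Ser,Asp,Ala,Bip,,1,43.6,6.37,ala_scan,1
RXL-3009,His,Aib,Glu,Gly,Thr,Phe(2-F),Thr,Ser,Asp,Bip,Ala,,1,43.2,6.00,ala_scan,1
RXL-3030,Aib,Aib,Glu,Gly,Thr,aMe-Phe(2-F),Thr,Ser,Asp,Bip,Bip,1.3,0,111.6,8.58,aib_scan,1
RXL-3031,His,Aib,Aib,Gly,Thr,aMe-Phe(2-F),Thr,Ser,Asp,Bip,Bip,4.0,0,121.3,8.31,aib_scan,1
RXL-3032,His,Aib,Glu,Aib,Thr,aMe-Phe(2-F),Thr,Ser,Asp,Bip,Bip,14.2,0,117.7,7.80,aib_scan,1
RXL-3033,His,Aib,Glu,Gly,Aib,aMe-Phe(2-F),Thr,Ser,Asp,Bip,Bip,6.9,0,119.9,8.13,aib_scan,1
RXL-3028,His,Aib,Glu,Gly,Thr,Aib,Thr,Ser,Asp,Bip,Bip,161.0,0,76.1,6.98,aib_scan,1
RXL-3034,His,Aib,Glu,Gly,Thr,aMe-Phe(2-F),Aib,Ser,Asp,Bip,Bip,80.2,0,105.7,7.04,aib_scan,1
RXL-3035,His,Aib,Glu,Gly,Thr,aMe-Phe(2-F),Thr,Aib,Asp,Bip,Bip,111.0,0,79.1,6.89,aib_scan,1
RXL-3036,His,Aib,Glu,Gly,Thr,aMe-Phe(2-F),Thr,Ser,Aib,Bip,Bip,67.5,0,96.7,7.04,aib_scan,1
RXL-3051,His,Aib,Glu,Gly,Thr,aMe-Phe(2-F),Thr,Ser,Asp,Aib,Bip,,1,26.8,6.00,aib_scan,1
RXL-3052,His,Aib,Glu,Gly,Thr,aMe-Phe(2-F),Thr,Ser,Asp,Bip,Aib,7.4,0,112.3,8.08,aib_scan,1
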