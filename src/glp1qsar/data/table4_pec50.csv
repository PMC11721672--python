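position,role,aib_id,ala_id,pec50_aib,pec50_ala,dpec50_printed
6,parent,RXL-101,RXL-3000,10.89,9.92,0.97
1,scan,RXL-3030,RXL-3001,8.58,7.86,-0.26
2,scan,RXL-101,RXL-3002,10.89,9.92,0.00
3,scan,RXL-3031,RXL-3003,8.31,8.47,-1.13
4,scan,RXL-3032,RXL-3037,7.80,6.46,0.37
5,scan,RXL-3033,RXL-3004,8.13,8.16,-1.00
6,scan,RXL-3028,RXL-3038,6.98,5.55,0.46
7,scan,RXL-3034,RXL-3005,7.04,7.67,-1.60
8,scan,RXL-3035,RXL-3006,6.89,8.72,-2.80
9,scan,RXL-3036,RXL-3007,7.04,8.32,-2.26
10,scan,RXL-3051,RXL-3008,6.00,6.37,-1.34
11,scan,RXL-3052,RXL-3009,8.08,6.00,1.11
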