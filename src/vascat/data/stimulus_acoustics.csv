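contrast_class,contrast,continuum_id,item,F1_Hz,F2_Hz,F3_Hz,duration_ms,VOT_ms,vowel_duration_ms,spectral_cog_Hz,dispersion_Hz
vowel,e/ae,pen-pan,pen,648,2011,2750,80,,,,
vowel,e/ae,pen-pan,pan,587,2252,2738,131,,,,
vowel,e/ae,bet-bat,bet,624,1812,2410,121,,,,
vowel,e/ae,bet-bat,bat,752,1814,2426,193,,,,
vowel,i/u,beet-boot,beet,274,2544,3197,140,,,,
vowel,i/u,beet-boot,boot,383,1548,2463,141,,,,
vowel,ae/a,hat-hot,hat,770,1777,2396,151,,,,
vowel,ae/a,hat-hot,hot,769,1237,2519,143,,,,
vowel,e/uh,net-nut,net,692,1875,2701,144,,,,
vowel,e/uh,net-nut,nut,729,1510,2397,127,,,,
stop_voicing,b/p,beach-peach,beach,,,,,4,146,,
stop_voicing,b/p,beach-peach,peach,,,,,45,107,,
stop_voicing,d/t,dime-time,dime,,,,,4,295,,
stop_voicing,d/t,dime-time,time,,,,,68,231,,
fricative_place,s/sh,sip-ship,ship,,,,,,,3527,1553
fricative_place,s/sh,sip-ship,sip,,,,,,,8005,1933
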