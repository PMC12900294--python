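trial_id,phase,objective,diets,replicates,total_tanks,sampling_dph,restock_at_41
Tr_1,I,baseline data collection,No. 1;No. 2;No. 3;No. 4;No. 5;No. 6;No. 7;No. 8;FSD;FSY,1,10,20;40;60;80,no
Tr_2,I,baseline data collection,No. 13;No. 14;No. 15;No. 16;No. 17;No. 18;No. 19;No. 20;No. 21;No. 22;FSD;FSY,1,12,20;40;60;80,no
Tr_3,II,BO exploration,No. 23;No. 24;No. 25;No. 26;No. 27;No. 28;No. 29;No. 30;No. 31;FSD;FSY,1,11,20;40;60;80,no
Tr_4,II,BO exploration,No. 31;No. 33;No. 34;No. 35;No. 36;No. 37;No. 38;No. 39;No. 40;FSD;FSY,1,11,20;40;60;80,no
Tr_5,III,BO exploitation and validation,No. 41;No. 41->No. 42;No. 41->No. 43;No. 41->No. 44;FSD;FSY,2,12,20;40;60;80;100,no
Tr_6,III,BO exploitation and validation,No. 41;No. 41->No. 42;No. 41->No. 43;No. 41->No. 44;FSD;FSY,2,12,20;40;60;80;100,no
Tr_7,IV,final validation,No. 41;No. 44;No. 41->No. 44;FSD;FSY;FSD->FSY,2,12,20;40;60;80;100,yes
Tr_8,IV,final validation,No. 41;No. 44;No. 41->No. 44;FSD;FSY;FSD->FSY,2,12,20;40;60;80;100,yes
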