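diet_id,egg_yolk_powder,skimmed_milk_powder,yeast_extract,soy_peptide,casein_na,cpsp,fish_oil,vitamin_mix,taurine,total
No. 1,16.1,10.8,0.0,10.8,10.8,43.0,4.3,2.2,2.2,100.0
No. 2,10.8,10.8,8.1,8.1,21.5,32.3,4.3,2.2,2.2,100.0
No. 3,2.7,0.0,26.9,0.0,32.3,33.9,0.0,2.2,2.2,100.0
No. 4,9.7,16.1,0.0,14.0,32.3,21.5,2.2,2.2,2.2,100.0
No. 5,16.1,16.1,26.9,0.0,10.8,25.8,0.0,2.2,2.2,100.0
No. 6,2.7,0.0,26.9,16.1,24.2,21.5,4.3,2.2,2.2,100.0
No. 7,5.4,0.0,16.1,16.1,31.2,25.8,1.1,2.2,2.2,100.0
No. 8,2.7,16.1,12.4,5.4,15.6,43.0,0.5,2.2,2.2,100.0
No. 13,16.1,16.1,0.0,16.1,41.9,5.4,0.0,2.2,2.2,100.0
No. 14,16.1,0.0,0.0,0.0,43.0,36.6,0.0,2.2,2.2,100.0
No. 15,0.0,0.0,26.9,16.1,10.8,41.9,0.0,2.2,2.2,100.0
No. 16,0.0,16.1,0.0,16.1,43.0,14.0,6.5,2.2,2.2,100.0
No. 17,0.0,16.1,26.9,0.0,40.9,5.4,6.5,2.2,2.2,100.0
No. 18,0.0,16.1,19.4,0.0,10.8,43.0,6.5,2.2,2.2,100.0
No. 19,0.0,9.7,0.0,0.0,43.0,43.0,0.0,2.2,2.2,100.0
No. 20,16.1,0.0,26.9,0.0,40.9,5.4,6.5,2.2,2.2,100.0
No. 21,16.1,16.1,26.9,16.1,10.8,9.7,0.0,2.2,2.2,100.0
No. 22,16.1,0.0,3.2,16.1,10.8,43.0,6.5,2.2,2.2,100.0
No. 23,16.6,8.4,2.1,10.1,29.7,28.8,0.0,2.1,2.1,100.0
No. 24,25.7,21.0,3.2,1.0,0.6,43.7,0.4,2.2,2.2,100.0
No. 25,26.5,1.1,0.1,13.1,43.7,9.9,1.3,2.2,2.2,100.0
No. 26,24.0,1.7,23.6,0.5,15.8,29.7,0.5,2.1,2.1,100.0
No. 27,26.7,1.6,9.9,5.4,5.8,46.2,0.2,2.2,2.2,100.0
No. 28,2.2,0.4,21.4,3.5,21.4,46.7,0.1,2.1,2.1,100.0
No. 29,16.2,0.0,0.0,0.0,43.0,36.6,0.0,2.2,2.2,100.0
No. 30,8.6,0.0,26.9,0.0,10.7,43.0,6.5,2.2,2.2,100.0
No. 31,19.4,19.4,15.1,0.0,38.7,0.0,3.2,2.2,2.2,100.0
No. 33,19.4,20.4,15.1,0.0,40.9,0.0,0.0,2.2,2.2,100.0
No. 34,15.8,24.6,1.7,13.0,39.5,0.5,0.5,2.2,2.2,100.0
No. 35,11.8,3.8,10.3,13.0,37.5,17.5,1.7,2.2,2.2,100.0
No. 36,10.8,18.9,18.7,0.8,37.7,2.3,6.6,2.2,2.2,100.0
No. 37,22.3,5.5,3.9,0.1,45.2,13.1,5.7,2.2,2.2,100.0
No. 38,19.9,8.5,7.7,0.9,46.9,7.8,4.0,2.2,2.2,100.0
No. 39,17.0,14.2,8.4,1.0,22.7,25.8,6.7,2.2,2.2,100.0
No. 40,10.3,5.7,9.0,7.3,33.5,27.5,2.3,2.2,2.2,100.0
No. 41,18.6,7.0,7.8,3.1,40.0,15.9,3.3,2.2,2.2,100.0
No. 42,25.3,5.5,17.8,0.1,27.3,18.9,0.8,2.2,2.2,100.0
No. 43,25.5,2.8,25.5,0.5,26.1,10.3,4.9,2.2,2.2,100.0
No. 44,22.1,20.2,13.5,0.2,33.4,4.8,1.4,2.2,2.2,100.0
FSD,16.0,16.0,0.0,5.3,21.3,31.9,5.3,2.1,2.1,100.0
FSY,10.8,10.8,16.1,0.0,21.5,32.3,4.3,2.2,2.2,100.0
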