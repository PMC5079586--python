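year,n,trips,pct_mature,pct_opt,pct_mega,mean_tl,sd_tl
1983,1299,89,17.2,12.4,4.8,54.7,11.5
1998,544,116,14.5,13.2,2.9,53.4,12.3
1999,160,131,20,17.5,2.5,52.5,13.4
2000,264,25,11,11.4,0.8,49.6,11.4
2001,553,,18.4,15.2,5.4,53.2,13.4
2002,292,104,11.6,11,1.7,49.8,13.3
2003,191,315,13.1,16.2,0.5,53.3,10.2
2009,663,,12.8,11.8,3.3,53,11.6
2011,314,51,10.5,10.5,1.9,52.2,10.7
2012,489,45,4.3,4.7,0.2,46.8,8.8
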