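year,source,tl_cm
1925,Stein Hoff,65.3
1925,Stein Hoff,76.0
1925,Stein Hoff,76.3
1934,R. Blomberg,60.3
1934,R. Blomberg,112.6
1934,R. Blomberg,82.7
1934,R. Blomberg,61.4
1934,R. Blomberg,62.8
1934,R. Blomberg,43.5
1934,R. Blomberg,74.2
1934,R. Blomberg,115.0
1934,R. Blomberg,83.2
1934,R. Blomberg,70.1
1934,R. Blomberg,70.4
1934,R. Blomberg,69.2
1934,R. Blomberg,78.6
1934,R. Blomberg,86.3
1934,R. Blomberg,77.0
1934,R. Blomberg,61.1
1934,R. Blomberg,74.4
1938,A. Hancock,87.8
1938,A. Hancock,91.7
1938,A. Hancock,76.7
1938,A. Hancock,71.0
1938,A. Hancock,87.1
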