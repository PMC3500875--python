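id,start,stop,event,X,Z
1,0.0,1.0,0,0,0.5
1,1.0,2.0,1,0,0.7
2,0.0,2.0,1,1,1.2
3,0.0,1.0,1,0,0.3
4,0.0,1.0,0,1,0.8
4,1.0,3.0,0,1,0.4
5,0.0,1.5,1,1,0.9
6,0.0,1.0,0,0,0.2
6,1.0,2.0,0,0,0.6
6,2.0,3.0,1,0,1.1
7,0.0,3.0,0,1,0.1
8,0.0,0.5,1,0,1.0
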