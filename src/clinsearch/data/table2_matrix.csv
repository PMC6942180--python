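support_level,P,S,B,D,N,I,S+N,P+N,B+D,B+N,D+N,N+I,P+S+D,S+D+N,D+N+I
full,4,0,7,0,0,0,0,0,0,0,0,0,0,0,0
accurate,1,0,0,8,0,0,0,1,3,0,5,0,0,0,0
broad,0,2,2,6,7,0,1,0,0,1,4,0,0,2,0
inaccurate,0,0,0,0,5,0,0,0,0,1,1,0,1,1,1
none,0,0,0,0,2,3,0,0,0,0,3,1,0,1,0
not_applicable,0,0,0,0,0,21,0,0,0,0,0,0,0,0,0
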