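subject,contour,change_class,ratio
A,MD,Decline,
B,MD,Decline,
C,MD,Decline,
D,MD,Decline,
E,MD,Decline,
A,LDF,Stable,
B,LDF,Stable,
C,LDF,Decline,
D,LDF,Stable,
E,LDF,Stable,
A,LDNF,Stable,
B,LDNF,Stable,
C,LDNF,Stable,
D,LDNF,Stable,
E,LDNF,Stable,
A,NDF,Stable,
B,NDF,Stable,
C,NDF,Decline,
D,NDF,Decline,
E,NDF,Decline,
A,NDNF,Stable,
B,NDNF,Stable,
C,NDNF,Stable,
D,NDNF,Stable,
E,NDNF,Stable,
A,CON,Stable,
B,CON,Stable,
C,CON,Stable,
D,CON,Stable,
E,CON,Stable,
A,HHV,Stable,
B,HHV,Stable,
C,HHV,Stable,
D,HHV,Stable,
E,HHV,Stable,
A,HLV,Decline,0.84
B,HLV,Decline,
C,HLV,Decline,
D,HLV,Decline,
E,HLV,Decline,
A,LLV,Stable,
B,LLV,Stable,
C,LLV,Stable,
D,LLV,Stable,
E,LLV,Stable,
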