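subject,contour,grade_label,artifact_suspect
A,HHV,no significant,False
B,HHV,no significant,False
C,HHV,no significant,False
D,HHV,minimal,True
E,HHV,minimal,True
A,HLV,marked,False
B,HLV,mild-moderate,False
C,HLV,moderate,False
D,HLV,moderate,False
E,HLV,moderate,False
A,LLV,minimal-mild,False
B,LLV,no significant,False
C,LLV,minimal,False
D,LLV,minimal,False
E,LLV,minimal,False
A,MD,moderate-marked,False
B,MD,mild-moderate,False
C,MD,moderate-marked,False
D,MD,moderate,False
E,MD,moderate,False
A,LDF,no significant,False
B,LDF,moderate-marked,False
C,LDF,moderate,False
D,LDF,minimal,False
E,LDF,minimal-mild,False
A,LDNF,no significant,False
B,LDNF,no significant,False
C,LDNF,no significant,False
D,LDNF,no significant,False
E,LDNF,no significant,False
A,NDF,no significant,False
B,NDF,no significant,False
C,NDF,mild-moderate,False
D,NDF,no significant,False
E,NDF,no significant,False
A,NDNF,mild,False
B,NDNF,no significant,False
C,NDNF,no significant,False
D,NDNF,minimal,False
E,NDNF,no significant,False
A,CON,no significant,False
B,CON,no significant,False
C,CON,no significant,False
D,CON,no significant,False
E,CON,no significant,False
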