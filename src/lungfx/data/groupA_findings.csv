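subject,contour,change_class,collagen_present,diagnosis
A1,MD,Decline,1,red_blood_cell_proliferation
A1,MD,Decline,1,fibrosis
A1,MD,Decline,1,mineralization
A2,MD,Decline,1,red_blood_cell_proliferation
A2,MD,Decline,1,fibrosis
A3,MD,Decline,1,red_blood_cell_proliferation
A3,MD,Decline,1,fibrosis
A4,MD,Decline,0,red_blood_cell_proliferation
A4,MD,Decline,0,inflammation
A5,MD,Decline,0,inflammation
A1,CON,Stable,0,
A2,CON,Stable,0,
A3,CON,Stable,0,
A4,CON,Stable,0,
A5,CON,Stable,0,
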