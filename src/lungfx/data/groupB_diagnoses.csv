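subject,contour,diagnosis,strength_label
A,HLV,chondrocyte_necrosis,moderate
A,HLV,inflammation,marked
A,HLV,fibrosis,marked
A,HLV,histiocytosis,moderate
A,HLV,multinucleated_giant_cells,mild
A,HLV,bronchitis,moderate
A,HLV,bronchial_ulceration,moderate
B,HLV,chondrocyte_necrosis,mild
B,HLV,inflammation,moderate
B,HLV,fibrosis,moderate
B,HLV,histiocytosis,moderate
B,HLV,bronchitis,moderate
C,HLV,chondrocyte_necrosis,moderate
C,HLV,inflammation,moderate
C,HLV,fibrosis,moderate
C,HLV,histiocytosis,moderate
C,HLV,multinucleated_giant_cells,mild
C,HLV,bronchitis,moderate
C,HLV,bronchial_ulceration,moderate
D,HLV,chondrocyte_necrosis,moderate
D,HLV,inflammation,mild
D,HLV,fibrosis,moderate
D,HLV,histiocytosis,moderate
E,HLV,chondrocyte_necrosis,moderate
E,HLV,inflammation,moderate
E,HLV,fibrosis,mild
E,HLV,multinucleated_giant_cells,mild
C,HHV,multinucleated_macrophages,minimal
D,HHV,fibrosis,minimal
D,HHV,inflammation,mild
E,HHV,histiocytosis,minimal
A,LLV,chondrocyte_necrosis,mild-moderate
A,LLV,inflammation,mild
A,LLV,fibrosis,minimal-mild
B,LLV,chondrocyte_necrosis,minimal
C,LLV,chondrocyte_necrosis,mild
C,LLV,inflammation,mild
C,LLV,fibrosis,minimal
D,LLV,chondrocyte_necrosis,mild
D,LLV,inflammation,mild
D,LLV,fibrosis,minimal
E,LLV,chondrocyte_necrosis,minimal
A,MD,chondrocyte_necrosis,moderate
A,MD,inflammation,marked
A,MD,fibrosis,marked
A,MD,type2_pneumocyte_hyperplasia,mild
A,MD,alveolar_septa_thickening,moderate
A,MD,multinucleated_giant_cells,mild
A,MD,histiocytosis,moderate
A,MD,proteinaceous_fluid,moderate
A,MD,vascular_proliferation,mild
B,MD,chondrocyte_necrosis,moderate
B,MD,inflammation,moderate
B,MD,fibrosis,moderate
B,MD,type2_pneumocyte_hyperplasia,mild
B,MD,alveolar_septa_thickening,moderate
B,MD,histiocytosis,moderate
B,MD,bronchitis,moderate
B,MD,bronchial_ulceration,moderate
B,MD,proteinaceous_fluid,mild
C,MD,chondrocyte_necrosis,moderate
C,MD,inflammation,moderate
C,MD,fibrosis,marked
C,MD,type2_pneumocyte_hyperplasia,mild
C,MD,alveolar_septa_thickening,moderate
C,MD,multinucleated_giant_cells,mild
C,MD,histiocytosis,moderate
C,MD,bronchitis,moderate
C,MD,bronchial_ulceration,moderate
C,MD,vascular_proliferation,moderate
C,MD,neovascularization,moderate
C,MD,vascular_necrosis,moderate
C,MD,proteinaceous_fluid,moderate
D,MD,chondrocyte_necrosis,moderate
D,MD,inflammation,moderate
D,MD,fibrosis,moderate
D,MD,type2_pneumocyte_hyperplasia,mild
D,MD,alveolar_septa_thickening,moderate
D,MD,multinucleated_giant_cells,mild
E,MD,chondrocyte_necrosis,moderate
E,MD,inflammation,moderate
E,MD,fibrosis,moderate
E,MD,type2_pneumocyte_hyperplasia,mild
E,MD,multinucleated_giant_cells,mild
E,MD,bronchitis,moderate
A,LDF,chondrocyte_necrosis,mild
B,LDF,fibrosis,moderate
B,LDF,chondrocyte_necrosis,minimal-mild
C,LDF,fibrosis,moderate
C,LDF,inflammation,moderate
C,LDF,neovascularization,mild
D,LDF,fibrosis,minimal
E,LDF,fibrosis,minimal
E,LDF,inflammation,minimal
A,LDNF,multinucleated_macrophages,minimal
B,LDNF,multinucleated_macrophages,minimal
B,LDNF,chondrocyte_necrosis,minimal
C,LDNF,multinucleated_macrophages,minimal
D,LDNF,multinucleated_macrophages,minimal
D,LDNF,chondrocyte_necrosis,minimal
E,LDNF,multinucleated_macrophages,minimal
C,NDF,fibrosis,moderate
C,NDF,inflammation,moderate
C,NDF,chondrocyte_necrosis,mild
C,NDF,vascular_proliferation,mild
C,NDF,multinucleated_giant_cells,mild
C,NDF,histiocytosis,mild
C,NDF,proteinaceous_fluid,mild
D,NDF,histiocytosis,mild
E,NDF,inflammation,mild
E,NDF,fibrosis,moderate
A,NDNF,fibrosis,minimal-mild
A,NDNF,inflammation,minimal-mild
A,NDNF,chondrocyte_necrosis,minimal
A,NDNF,multinucleated_giant_cells,minimal
A,NDNF,vascular_proliferation,minimal
B,NDNF,inflammation,minimal
D,NDNF,fibrosis,mild
D,NDNF,inflammation,minimal-mild
D,NDNF,chondrocyte_necrosis,minimal
D,NDNF,multinucleated_giant_cells,minimal
D,NDNF,vascular_proliferation,minimal
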