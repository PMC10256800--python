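{
 "groupA_findings.csv": "d040f88ea15bfcd3449453f2f4bb5045583bd28da5ba51790d89028499cbaa32",
 "groupB_collagen.csv": "2b8b846b914eaefcc15e7aceb5a96791add888901940a15ce2ab021e8c04323e",
 "groupB_diagnoses.csv": "872bedd53919743f5d1cbdbc6f9b6b9d15d92368de88f9082a75eb7fa3eb73ed",
 "groupB_ventilation.csv": "099b5937aaf8e392a55cd7c289e5f6daa121d44759c6fc52d49e8d3243170945"
}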