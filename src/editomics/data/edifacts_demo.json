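{
 "records": [
  {
   "id": 44,
   "name": "PPR_71",
   "species": "Physcomitrella patens",
   "organelle": "mitochondrion",
   "target_sites": [["ccmFC", "ccmFCeU122SF"]],
   "n_ppr": 21,
   "c_terminal": ["E1", "E2", "DYW"],
   "protein_ref": "demo:PPR_71",
   "publications": ["demo entry (synthetic citation placeholder)"]
  },
  {
   "id": 45,
   "name": "PPR_65",
   "species": "Physcomitrella patens",
   "organelle": "mitochondrion",
   "target_sites": [["ccmFC", "ccmFCeU103PS"]],
   "n_ppr": 21,
   "c_terminal": ["E1", "E2", "DYW"],
   "protein_ref": "demo:PPR_65",
   "publications": ["demo entry (synthetic citation placeholder)"]
  }
 ],
 "synonyms": {
  "ccmFC": ["ccmFc", "ccb452", "ccb6"]
 }
}
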