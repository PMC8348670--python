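{
  "schema_version": 1,
  "channel": "kcsa",
  "comment": "KcsA map (fits 1bl8/2boc/2hvj/2w0f/3stl chains A-D). Anchored on the filter fingerprint: TVGYG tyrosine Y78 = p52, hence A73 = p47, T74 = p48, T75 = p49; P1 helix spans p38-p47 (residues 64-73). Inner helix TM2: gating-hinge G99 = i14, so i1 = residue 86 (I100 = i15, F103 = i18).",
  "entries": [
    {"repeat": 1, "segment": "o", "chain": "A", "first_resseq": 27, "first_index": 1, "length": 25, "optional": true},
    {"repeat": 1, "segment": "p", "chain": "A", "first_resseq": 62, "first_index": 36, "length": 18},
    {"repeat": 1, "segment": "i", "chain": "A", "first_resseq": 86, "first_index": 1, "length": 29, "optional": true},
    {"repeat": 2, "segment": "o", "chain": "B", "first_resseq": 27, "first_index": 1, "length": 25, "optional": true},
    {"repeat": 2, "segment": "p", "chain": "B", "first_resseq": 62, "first_index": 36, "length": 18},
    {"repeat": 2, "segment": "i", "chain": "B", "first_resseq": 86, "first_index": 1, "length": 29, "optional": true},
    {"repeat": 3, "segment": "o", "chain": "C", "first_resseq": 27, "first_index": 1, "length": 25, "optional": true},
    {"repeat": 3, "segment": "p", "chain": "C", "first_resseq": 62, "first_index": 36, "length": 18},
    {"repeat": 3, "segment": "i", "chain": "C", "first_resseq": 86, "first_index": 1, "length": 29, "optional": true},
    {"repeat": 4, "segment": "o", "chain": "D", "first_resseq": 27, "first_index": 1, "length": 25, "optional": true},
    {"repeat": 4, "segment": "p", "chain": "D", "first_resseq": 62, "first_index": 36, "length": 18},
    {"repeat": 4, "segment": "i", "chain": "D", "first_resseq": 86, "first_index": 1, "length": 29, "optional": true}
  ]
}
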