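{
  "schema_version": 1,
  "channel": "kv1.2-kv2.1-chimera-2r9r",
  "comment": "Template map, anchored on the selectivity-filter fingerprint: GYG tyrosine Y377 = p52, so the filter threonines T373/T374 sit at p48/p49 and the P1 helix spans p37-p47. Inner-helix indexing anchors the gating-hinge glycine region at i14. Chains A-D are the channel subunits, arranged I-IV.",
  "entries": [
    {"repeat": 1, "segment": "o", "chain": "A", "first_resseq": 332, "first_index": 1, "length": 26, "optional": true},
    {"repeat": 1, "segment": "p", "chain": "A", "first_resseq": 362, "first_index": 37, "length": 17},
    {"repeat": 1, "segment": "i", "chain": "A", "first_resseq": 384, "first_index": 1, "length": 32, "optional": true},
    {"repeat": 2, "segment": "o", "chain": "B", "first_resseq": 332, "first_index": 1, "length": 26, "optional": true},
    {"repeat": 2, "segment": "p", "chain": "B", "first_resseq": 362, "first_index": 37, "length": 17},
    {"repeat": 2, "segment": "i", "chain": "B", "first_resseq": 384, "first_index": 1, "length": 32, "optional": true},
    {"repeat": 3, "segment": "o", "chain": "C", "first_resseq": 332, "first_index": 1, "length": 26, "optional": true},
    {"repeat": 3, "segment": "p", "chain": "C", "first_resseq": 362, "first_index": 37, "length": 17},
    {"repeat": 3, "segment": "i", "chain": "C", "first_resseq": 384, "first_index": 1, "length": 32, "optional": true},
    {"repeat": 4, "segment": "o", "chain": "D", "first_resseq": 332, "first_index": 1, "length": 26, "optional": true},
    {"repeat": 4, "segment": "p", "chain": "D", "first_resseq": 362, "first_index": 37, "length": 17},
    {"repeat": 4, "segment": "i", "chain": "D", "first_resseq": 384, "first_index": 1, "length": 32, "optional": true}
  ]
}
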