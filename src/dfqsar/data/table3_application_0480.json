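{
 "assay": "OT_ER_ERbERb_0480",
 "tp": 162,
 "fp": 1280,
 "fn": 13,
 "tn": 350
}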