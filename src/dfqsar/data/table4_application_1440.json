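{
 "assay": "OT_ER_ERbERb_1440",
 "tp": 135,
 "fp": 1304,
 "fn": 15,
 "tn": 346
}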