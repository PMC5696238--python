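compound_id,eadb_label,toxcast_outcome
SHARED01,binder,active
SHARED02,binder,active
SHARED03,binder,active
SHARED04,binder,active
SHARED05,binder,active
SHARED06,binder,active
SHARED07,binder,active
SHARED08,binder,active
SHARED09,binder,active
SHARED10,binder,active
SHARED11,binder,active
SHARED12,binder,active
SHARED13,binder,active
SHARED14,binder,active
SHARED15,binder,active
SHARED16,binder,inactive
SHARED17,binder,inactive
SHARED18,binder,inactive
SHARED19,binder,inactive
SHARED20,binder,inactive
SHARED21,binder,inactive
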