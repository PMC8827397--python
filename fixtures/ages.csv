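core_id,age_at_first
C001,56
C002,35
C003,44
C004,26
C005,60
C006,49
C007,69
C008,29
C009,32
C010,29
C011,26
C012,52
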