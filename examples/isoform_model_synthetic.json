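{
 "RA": ["e1", "e2", "e3", "e4", "e5", "e6", "e7", "e9", "e10"],
 "RB": ["e1", "e2", "e3", "e4", "e5", "e6", "e7", "e8", "e9", "e10"],
 "RC": ["e3", "e4", "e5", "e6", "e7", "e9", "e10"],
 "RD": ["e1", "e2", "e3", "e4", "e5", "e8", "e9", "e10"],
 "RE": ["e1", "e2", "e3", "e4", "e5", "e6", "e7", "e9", "e11"],
 "RF": ["e1", "e2", "e3", "e5", "e6", "e7", "e9", "e10"]
}
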