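donor_exon	acceptor_exon	count
e1	e2	900
e2	e3	920
e3	e4	880
e3	e5	30
e4	e5	890
e5	e6	850
e5	e8	40
e6	e7	860
e7	e8	420
e7	e9	470
e8	e9	450
e9	e10	820
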