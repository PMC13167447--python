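# Fluo-4 rundown: amplitudes step down after the 15-min recordings.
base: paper_table_s1
optics: {dye: fluo4}
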