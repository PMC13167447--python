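base: paper_table_s1
optics: {dye: calbryte520}
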