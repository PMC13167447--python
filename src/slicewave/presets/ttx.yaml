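# Na+ channel blockade: no spikes, hence no downstream events at all.
base: paper_table_s1
events: {pharm: ttx}
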