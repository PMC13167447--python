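# NBQX + D-AP5: glutamatergic transmission blocked; the direct spike and
# pre-synaptic Ca2+ influx survive, EPSPs and postsynaptic Ca2+ do not.
base: paper_table_s1
events: {pharm: iglur_block}
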