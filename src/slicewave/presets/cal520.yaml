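# Cal520 run-up: amplitudes grow linearly by ~8% of the initial amplitude
# every 5 minutes of the session.
base: paper_table_s1
optics: {dye: cal520}
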