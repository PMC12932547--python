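# Compositional null: no real signal, but a bloomer taxon surges 20-fold
# in the two cultivated groups and drags total microbial load with it.
builtin: null_load_shift
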