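# Ten taxa enriched 4-fold (absolute scale) in the wild group, plus a
# host-specific reference taxon absent from all companion groups.
builtin: planted_signal
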