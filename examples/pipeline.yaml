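# Full pipeline configuration (paths are relative to where you run `irmdma run`).
table: sim/percent.tsv
design: sim/design.tsv
out_dir: results
unit: percent
irm: auto          # or a genus name to skip the screen
detection_limit: 0.002
irm_threshold: 0.005
abundance_threshold: 0.005
alpha: 0.05
mode: per_sample
groups: [wild, cult1, cult2]
reference: wild
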