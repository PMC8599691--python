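# Demo pipeline run on simulated inputs (written under <out_dir>/sim).
# The score cuts are set for the synthetic score scale; on cohort data scored
# like the published analysis the defaults are low_cut: 0, high_cut: 10.
out_dir: results/demo
seed: 7
simulate: true
low_cut: -0.5
high_cut: 0.5
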