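# Example scenario for `sinswitch run --config ...`
# Normal starvation course, two strains, small ensemble.
scenario: normal
strains: [WT, dsda]
n_lineages: 100
t_end: 14.0
sample_dt: 0.5
seed: 1
outdir: results
thresholds:
  mu_spo: 0.17
  tapa_on: 500.0
  observation_time: 8.0
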