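# Study conditions for the synthetic comparative analysis: three diverged
# populations (two "selected" meat-type lines and one control line), each
# with a planted selective sweep, plus a 4-vs-4 expression contrast with
# planted differentially expressed genes.
seed: 11
outdir: results/study
simulate:
  n_pops: 3
  samples_per_pop: 8
  pop_names: [meat_a, meat_b, control]
  chrom_lengths: {chr1: 6000000, chr2: 4000000}
  n_snps: 50000
  fst_background: 0.05
  frac_low_qual: 0.05
  missing_rate: 0.01
  sweep_regions:
    - {chrom: chr1, start: 1000000, end: 1400000, selected_pop: meat_a,
       diversity_reduction: 0.2, differentiation_boost: 0.3}
    - {chrom: chr1, start: 3000000, end: 3400000, selected_pop: meat_b,
       diversity_reduction: 0.2, differentiation_boost: 0.3}
    - {chrom: chr2, start: 1500000, end: 1900000, selected_pop: control,
       diversity_reduction: 0.2, differentiation_boost: 0.3}
  rnaseq: {n_genes: 2000, n_per_group: 4, dispersion: 0.1, n_de: 200, lfc_de: 2.0}
params:
  n_boot: 100
comparisons:
  - {selected: meat_a, control: control}
  - {selected: meat_b, control: control}
  - {selected: control, control: meat_a}
  - {selected: control, control: meat_b}
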