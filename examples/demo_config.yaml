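# Synthetic end-to-end demo: simulate a two-chromosome panel with planted
# homozygous tracts and one selective sweep, then run every stage.
out_dir: demo_out
genotypes: demo_out/synthetic
haplotypes: demo_out/synthetic
seed: 11

simulate:
  n_ind: 30
  chromosomes: [[1, 30000000], [2, 30000000]]
  snp_spacing: 51000
  missing_rate: 0.01
  seed: 11
  roh:
    - {individual: ind0, chromosome: 1, start: 3000000, length: 6000000}
    - {individual: ind0, chromosome: 2, start: 10000000, length: 4000000}
    - {individual: ind1, chromosome: 1, start: 12000000, length: 3000000}
  sweeps:
    - {chromosome: 2, core_position: 20000000, derived_freq: 0.3, shared_length: 1000000}

qc: {max_ind_missing: 0.10, max_snp_missing: 0.05}
roh: {window_snp: 40}
islands: {min_incidence: 20, tail: 0.001}
scan: {maf_min: 0.05, bin_width: 0.025}
pca: {window_snp: 50, step_snp: 10, r2_max: 0.1, n_components: 5}
annotation: {path: examples/demo_genes.gff3}
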