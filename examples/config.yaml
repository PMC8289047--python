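# Full synthetic pipeline: simulate a weakly differentiated two-population
# panel with a spiked selected region, calibrate the neutral null, run the
# divergence scan and the dosage test, and generate phenotype/expression
# fixtures for the correlation stage.
#
#   altiscan run --config examples/config.yaml --seed 7 --out results/

seed: 7
out_dir: results

# demography: defaults are the fitted colonization scenario; override any key
demography:
  N_high: 85058.0
  T_split: 2598.0
  m_low_to_high: 0.08

sample:
  n_high: 11
  n_low: 12
  n_sites: 5000

spike:
  n_spiked: 25
  delta_freq: 0.9
  region: [sim_1, 200000, 250000]

calibration:
  n_loci: 400
  sites_per_locus: 410

scan:
  window_bp: 50000
  hd_min_per_window: 13
  max_outlier_windows: 1000
  fst_quantile: 0.99
  pi_ratio_quantile: 0.95

make_pheno:
  n_high: 4
  n_low: 4
  n_traits: 3
  n_genes: 100
  n_coupled: 10
  coupling_r: 0.9

alpha: 0.05
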