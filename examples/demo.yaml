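# Desk-scale demo: 120 synthetic subjects x 400 regions, full pipeline.
# Permutation counts are reduced from the analysis defaults (1000 / 10000)
# so the run stays interactive (~3 minutes on one CPU).
n_regions: 400
n_ad: 60
n_nc: 60
n_sites: 2
effect_sd: 0.5
site_offset_sd: 0.2
n_genes: 2000
n_planted: 50
planted_corr: 0.9
svr_c_grid: [0.1, 1.0, 10.0]
svr_eps_grid: [0.1]
svr_n_perm: 49
pls_n_perm: 1000
pls_n_boot: 1000
seed: 7
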