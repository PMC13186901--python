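# Default (scaled-down) virtual-trial configuration: the 50-59-year-old male
# cell at the coarse solver grid.  Field names mirror TrialConfig.
sexes: [male]
age_groups: ["50-59"]
n_per_group: 256
seed: 11
diseases: [dm_htn, dm_htn_dkd, dm_htn_hkd]
target_dx: 0.013
cfl: 0.9
min_cells: 2
heart_rate: 75.0
filter_sbp_sd: 1.9
filter_dbp_sd: 1.4
filter_z: 2.575
ri_interval: [0.47, 0.80]
dkd_afferent_scale: 1.10
dkd_efferent_scale: 0.93
dkd_surviving_fraction: 0.43
hkd_interlobular_pvr_ratio: 1.10
holdout_iters: 50
train_frac: 0.70
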