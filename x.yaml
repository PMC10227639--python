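reference_path: null
scats_path: scats.csv
bears_path: bears.csv
out_dir: out
renormalize_vf: false
vf_closure_tol: 0.5
misc_threshold_pct: 5.0
misc_cf: null
dm_threshold: 3.55
kj_per_g_protein: 16.72
kj_per_g_fat: 37.62
kj_per_g_nfe: 16.72
spring_start: {}
fall_end:
- 10
- 31
alpha: 0.05
df_method: residual
responses:
- cp_dm
- nonfat_fat_dm
seed: 0
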