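# Example end-to-end configuration for `riverdom run-all --config ...`.
output_dir: riverdom_out
seed: 1
season: recovery        # fluorophore set: dry | wet | recovery (3 components)
n_samples: 20
n_taxa: 40
depth: 20000
scatter: true
n_starts: 4
max_iter: 800
r_min: 0.5
p_max: 0.05
ex_hix: 254.0
zero_tol: 0.05
order_variable: sample_id
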