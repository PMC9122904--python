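# demo pipeline configuration: `chaperkit report --config examples/run.toml`
seed = 7
out_dir = "chaperkit_out"
stages = ["simulate", "fit-kinetics", "titrate", "pre", "compare-pre",
          "ensemble", "occupancy"]

[kinetics]
k_on = 1e5      # 1/(M s)
k_off = 0.01    # 1/s
noise_frac = 0.01

[titration]
kd_mM = 4.7
dmax_ppm = 0.1
p0_mM = 0.1
noise_sd_ppm = 0.005

[pre]
threshold = 2.0
ratio_cap = 10.0

[ensemble]
n_conformers = 400
keep_frac = 0.1
top_k = 3
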