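# Reduced-scale synthetic run: `breakscape run examples/config.toml`
mode = "synthetic"
seed = 11
outdir = "scratch/example_run"

[simulate]
n_candidate_sites = 120
n_cleaved = 30
n_hr = 10
n_nhej = 10

[simulate.chrom_spec]
chr1 = 6000000
chr2 = 6000000
chrY = 2000000

[bless]
window_bp = 1000
max_len = 500
top_k = 25

[classify]
numerator = "RAD51"
denominator = "XRCC4"
k = 10

[controls]
n_pool = 400
n_out = 40
min_dist = 200000
exclude_top = 50

[signature]
damage_windows = [1000, 1000000]
multiscale_windows = [1000, 2000, 4000, 10000, 1000000]
basal_window = 4000

[profile]
features = ["gH2AX", "H2AZ", "H2BK120ac"]
half_window = 1000000
smooth_span = 50000
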