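"""Draw the random control-region background set.

1000 positions uniform over the non-Y genome, kept only if at least 1 Mb from
every top-150 cleaved site and showing non-zero coverage in every checked
track; 80 survivors are sampled as the controls used by the signature tests.
"""

from _common import RESULTS, STUDY_SEED, call_breaks, simulate_study
from breakscape.controls import generate_controls
from breakscape.io import write_table
from breakscape.simulate import simulate_chip

cfg, chromsizes, sites, truth, fragments = simulate_study()
result = call_breaks(cfg, chromsizes, sites, fragments)

top150 = result.table.nsmallest(150, "rank")["site_id"]
tracks = []
for name in ("RAD51", "XRCC4", "gH2AX"):
    damaged, undamaged = simulate_chip(cfg, chromsizes, sites, truth, name)
    tracks.extend([damaged, undamaged])

controls = generate_controls(
    chromsizes, sites.subset(list(top150)), tracks, seed=STUDY_SEED + 1
)
write_table(controls.to_frame(), RESULTS / "control_regions.tsv")

print(f"{len(controls)} control regions drawn (seed {STUDY_SEED + 1})")
print("all controls are >= 1 Mb from the top-150 cleaved sites, off chrY, "
      "and non-zero in every checked track")
print(f"wrote {RESULTS / 'control_regions.tsv'}")
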