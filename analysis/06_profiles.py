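"""Averaged enrichment profiles around the validated breaks at two scales.

Mb-scale features (phospho-H2AX-like, ubiquitin, linker histone H1) are shown
as log2 damaged/undamaged ratios over a 10 Mb window smoothed with a 50 kb
span; kb-scale features over a 20 kb window at bin resolution.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, call_breaks, simulate_study
from breakscape.core import average_profile, log2_ratio_track
from breakscape.io import write_table
from breakscape.simulate import simulate_chip

cfg, chromsizes, sites, truth, fragments = simulate_study()
result = call_breaks(cfg, chromsizes, sites, fragments)
validated = sites.subset(result.validated_ids)

panels = [
    ("gH2AX", 5_000_000, 50_000, 20_000),
    ("ubiquitin", 5_000_000, 50_000, 20_000),
    ("H1", 5_000_000, 50_000, 20_000),
    ("H2BK120ub", 10_000, 0, 200),
    ("H2BK120ac", 10_000, 0, 200),
    ("macroH2A", 10_000, 0, 200),
]
rows = []
for name, half, span, step in panels:
    damaged, undamaged = simulate_chip(cfg, chromsizes, sites, truth, name)
    ratio = log2_ratio_track(damaged, undamaged)
    offsets, prof = average_profile(
        ratio, validated, half, smooth_span=span, chromsizes=chromsizes, step=step
    )
    rows.append(pd.DataFrame(
        {"feature": name, "offset": offsets, "log2_ratio": np.round(prof, 4)}
    ))
    centre = np.nanmean(prof[np.abs(offsets) < half // 50])
    edge = np.nanmean(prof[np.abs(offsets) > 0.9 * half])
    print(f"{name:>10}: centre {centre:+.3f}  edge {edge:+.3f}  "
          f"({2 * half / 1e6:g} Mb window)")

profiles = pd.concat(rows, ignore_index=True)
write_table(profiles, RESULTS / "average_profiles.tsv")
print(f"wrote {RESULTS / 'average_profiles.tsv'}")
print("Mb-scale features keep their sign across the spreading domain and decay "
      "to ~0 outside it; kb-scale features are confined to a few kb around the cut.")
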