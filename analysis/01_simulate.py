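"""Generate the synthetic study: genome, candidate sites, truth and fragments.

Emulates an enzyme-induced break-mapping experiment: 1,211 candidate
recognition sites on a 156 Mb six-chromosome genome, 174 of them truly
cleaved with efficiencies uniform on [0.1, 1], break-labelling fragments
piling up at cut positions over a uniform background.
"""

import pandas as pd

from _common import RESULTS, simulate_study
from breakscape.io import write_table

cfg, chromsizes, sites, truth, fragments = simulate_study()

lens = fragments["end"] - fragments["start"]
summary = pd.DataFrame(
    [
        ("chromosomes", len(chromsizes)),
        ("genome_bp", sum(chromsizes.values())),
        ("candidate_sites", len(sites)),
        ("sites_on_chrY", sum(s.chrom == "chrY" for s in sites)),
        ("cleaved_sites", int(truth.table["cleaved"].sum())),
        ("hr_labelled", len(truth.pathway_ids("HR"))),
        ("nhej_labelled", len(truth.pathway_ids("NHEJ"))),
        ("fragments_emitted", len(fragments)),
        ("fragments_over_500bp", int((lens > 500).sum())),
        ("median_fragment_bp", int(lens.median())),
    ],
    columns=["quantity", "value"],
)
RESULTS.mkdir(exist_ok=True)
write_table(summary, RESULTS / "simulation_summary.tsv")

print(summary.to_string(index=False))
print(f"\nwrote {RESULTS / 'simulation_summary.tsv'}")
print("The minority of candidate sites carries true cleavage, with pathway "
      "labels placed on the most efficiently cut sites; fragments over 500 bp "
      "are the aberrant tail the caller must drop.")
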