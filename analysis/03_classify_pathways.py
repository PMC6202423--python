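"""Split the 80 validated breaks into HR-prone and NHEJ-prone classes.

The score is the ratio of resection-factor signal (RAD51, 4 kb window) to
end-joining-factor signal (XRCC4, 1 kb window); top 30 ratios -> HR-prone,
bottom 30 -> NHEJ-prone, the middle 20 left unassigned.
"""

import pandas as pd

from _common import RESULTS, call_breaks, classify_breaks, simulate_study
from breakscape.io import write_table

cfg, chromsizes, sites, truth, fragments = simulate_study()
result = call_breaks(cfg, chromsizes, sites, fragments)
call = classify_breaks(cfg, chromsizes, sites, truth, result.validated_ids)

out = call.table.copy()
out["ratio"] = out["ratio"].round(4)
out = out.merge(truth.table[["site_id", "pathway"]].rename(
    columns={"pathway": "true_pathway"}), on="site_id")
write_table(out, RESULTS / "pathway_labels.tsv")

confusion = pd.crosstab(out["true_pathway"], out["label"])
print(confusion)
true_hr = set(truth.pathway_ids("HR")) & set(result.validated_ids)
recovered = len(set(call.ids("HR")) & true_hr) / len(true_hr)
print(f"\nHR label recovery among validated true-HR sites: {recovered:.2%}")
print(f"wrote {RESULTS / 'pathway_labels.tsv'}")
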