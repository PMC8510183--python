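"""Simulate a storage experiment and look at what was planted.

Generates the default design — four sample matrices (two pig feces, two
sewage), stored at −80/−20/5/22 °C for 16 h or 64 h plus an unstored 0 h
reference, in triplicate, spiked and unspiked, with a freeze-thaw series —
and prints the table shapes and a slice of the ground truth.
"""

import storagefx as sx

ds = sx.generate_dataset(seed=1)

print(f"taxa counts:  {ds.taxa.shape[0]} genera x {ds.taxa.shape[1]} samples")
print(f"AMR counts:   {ds.amr.shape[0]} genes x {ds.amr.shape[1]} samples")
print(f"sample sheet: {len(ds.sheet)} samples, "
      f"{ds.sheet['condition'].nunique()} conditions")

# the planted warm-storage effect: Firmicutes gain at 22 C over time
phylum = ds.taxa_meta["phylum"]
firmicutes = phylum.index[phylum == "Firmicutes"]
sheet = ds.sheet
for cond in ("0h", "16h_22C", "64h_22C"):
    sid = sheet.index[
        (sheet["matrix"] == "P1") & (sheet["condition"] == cond) & (~sheet["spiked"])
    ][0]
    share = ds.truth.expected_relative.loc[firmicutes, sid].sum()
    print(f"P1 {cond:>8}: expected Firmicutes share = {share:.3f}")
# The share rises with time at 22 C: warm storage lets Firmicutes and
# Actinobacteria overgrow while Bacteroidetes/Proteobacteria decline.
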