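"""The two-step k-mer baseline: tabulate fragment pH values, then average.

Every training k-mer is associated with its source sequence's pH; a query
is scored by the occurrence-weighted mean of its k-mers' tabulated means.
The literal mode counts untabulated k-mers as 0 in the average (faithful
to the defining dot product); present_only divides by matched occurrences
instead and falls back to the training median when nothing matches.
"""

import numpy as np

from ophpred import SimulationConfig, simulate_dataset
from ophpred.curation import curate_optimal_ph
from ophpred.evaluation import mae
from ophpred.kmer import build_kmer_table, predict_kmer_ph, predict_kmer_range
from ophpred.splitting import random_split

sim = simulate_dataset(SimulationConfig(seed=3))
dataset, _ = curate_optimal_ph(sim.measurements, sim.records)
split = random_split(dataset, validation_fraction=0.25, seed=3)

train = dataset.subset(sorted(split.train_ids))
table = build_kmer_table(train, k=3)
print(f"k-mer table: {len(table)} distinct 3-mers from {len(train)} sequences")

val_ids = sorted(split.validation_ids)
y_val = [dataset.labels[i] for i in val_ids]
for mode in ("literal", "present_only"):
    preds = [predict_kmer_ph(table, dataset.record(i).sequence, mode) for i in val_ids]
    print(f"validation MAE ({mode:12s}): {mae(y_val, preds):.3f} pH units")

rid = val_ids[0]
lo, hi = predict_kmer_range(table, dataset.record(rid).sequence, "present_only")
point = predict_kmer_ph(table, dataset.record(rid).sequence, "present_only")
print(f"example range estimate for {rid}: [{lo:.2f}, {hi:.2f}] around point {point:.2f}"
      f" (true {dataset.labels[rid]:.2f})")
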