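"""Randomize injection order and interleave QC injections.

Randomizes 200 biological samples stratified by hospital, disease group,
sex, and age stratum into batches of 40, then fronts each batch with a
solvent blank and the standards-mixture calibration gradient and inserts a
(QC_mix, QC_bio, QC_NIST) triplet after every 10 biological injections.
"""

import numpy as np
import pandas as pd

from metaboflow import interleave_qc, randomize_order

rng = np.random.default_rng(0)
samples = pd.DataFrame({
    "sample_id": [f"S{i:04d}" for i in range(200)],
    "hospital": rng.choice(["NCH", "XYH", "TJH"], 200, p=[0.68, 0.27, 0.05]),
    "group": rng.choice(["HCtrl", "CRC", "NC"], 200),
    "sex": rng.choice(["male", "female"], 200),
    "age": rng.uniform(20, 85, 200),
})

sched = randomize_order(samples, batch_size=40, seed=7)
full = interleave_qc(sched, qc_period=10)

sizes = full.entries.groupby("batch")["sample_type"].value_counts().unstack()
print(sizes)
print(f"\ntotal injections: {len(full.entries)} "
      f"({len(samples)} biological + QC)")
print("Per batch: 40 bio + 1 blank + 6-point calibration gradient + 4 QC "
      "triplets = 59 injections; stratum counts differ by at most one "
      "between batches.")
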