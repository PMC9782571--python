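"""Differential analysis and tree-ensemble classification on a case/control
cohort.

Simulates a balanced two-group cohort with 20 informative features at log2
fold change 1, curates and merges the three platforms, runs the volcano
contrast (|log2FC| > 0.25, Welch p < 0.05), and evaluates gradient-boosted
trees with the stratified 75/25 split + successive-halving protocol.
"""

import numpy as np

from metaboflow import (SimulationConfig, coverage_filter, deduplicate,
                        differential, evaluate_classifiers, impute)
from metaboflow.analysis import runs_to_frame
from metaboflow.simulate import simulate_study

cfg = SimulationConfig(
    n_subjects=300, seed=8, group_fractions={"HCtrl": 0.5, "CRC": 0.5},
    case_groups=("CRC",), n_informative=20, effect_log2fc=1.0,
    n_features={"lc_polar": 80, "lc_lipid": 40, "gc": 20})
*_, tables, truth = simulate_study(cfg)
curated = {p: impute(coverage_filter(t, 0.5), lod=cfg.lod_intensity[p], seed=1)
           for p, t in tables.items()}
merged = deduplicate(curated).merged

contrast = differential(merged, ("CRC", "HCtrl"))
print(f"features tested      : {len(contrast.table)}")
print(f"significantly up     : {contrast.n_up}")
print(f"significantly down   : {contrast.n_down}")
hits = set(contrast.table.index[contrast.table.significant])
truth_ids = {f"{p}:{f}" for f in truth.informative_features
             for p in ("lc_polar", "lc_lipid", "gc")}
print(f"true informative hit : {len(hits & truth_ids)} of "
      f"{cfg.n_informative} injected")

labels = merged.sample_meta.loc[merged.bio_columns, "group"]
runs = evaluate_classifiers(merged, labels,
                            algorithms=("gradient_boosted_trees",),
                            n_repeats=3, seed=5)
frame = runs_to_frame(runs)
print(f"\ngradient-boosted trees, 3 repeats:")
print(frame[["split_seed", "f1_CRC", "f1_HCtrl", "f1_macro"]].round(3)
      .to_string(index=False))
print(f"mean macro F1        : {np.mean(frame.f1_macro):.3f}")
print("\nThe contrast should flag ~the injected informative features, and "
      "held-out F1 near 1 reflects the strong injected signal.")
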