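"""Remove injected batch effects with the QC-anchored adversarial autoencoder.

Simulates a cohort with strong inter-batch offsets (sd 0.5 on the log2
scale) plus injection-order drift, trains the adversarial autoencoder, and
compares the pooled-reference (QC_NIST) replicate CV before and after
correction against the TIC and median-scaling baselines.  Because QC_NIST
is one fixed plasma pool, any spread across its injections is technical.
"""

from metaboflow import (SimulationConfig, apply_normalization, assess,
                        coverage_filter, fit_normae, impute, normalize_median,
                        normalize_tic, qc_nist_cv)
from metaboflow.simulate import simulate_study

cfg = SimulationConfig(
    n_subjects=200, n_batches=5, seed=3, inter_batch_sd=0.5,
    n_features={"lc_polar": 100, "lc_lipid": 20, "gc": 20})
*_, tables, truth = simulate_study(cfg)
table = impute(coverage_filter(tables["lc_polar"], 0.5),
               lod=cfg.lod_intensity["lc_polar"], seed=2)

model = fit_normae(table, seed=0)
corrected = apply_normalization(model, table)
report = assess(table, corrected)

sub = table.subset_columns(table.columns_of_type("bio", "QC_bio", "QC_NIST"))
print(f"median QC_NIST CV raw        : {qc_nist_cv(table).median():6.1f} %")
print(f"median QC_NIST CV TIC        : {qc_nist_cv(normalize_tic(sub)).median():6.1f} %")
print(f"median QC_NIST CV median-scale: {qc_nist_cv(normalize_median(sub)).median():5.1f} %")
print(f"median QC_NIST CV autoencoder: {qc_nist_cv(corrected).median():6.1f} %")
print(f"QC cluster dispersion ratio  : {report.qc_dispersion_ratio:6.2f}")
print(f"epochs trained               : {len(model.history)}")
print("\nGlobal per-injection scalers (TIC/median) cannot remove "
      "feature-specific batch offsets; the adversarial autoencoder shrinks "
      "the pooled-reference CV several-fold and tightens its PCA cluster "
      "(dispersion ratio << 1).")
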