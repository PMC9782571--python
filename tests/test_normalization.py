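"""Scaling baselines and the adversarial autoencoder corrector."""

import numpy as np
import pandas as pd
import pytest

from metaboflow.containers import FeatureTable
from metaboflow.curation import coverage_filter, impute
from metaboflow.normalization import (NormAEConfig, apply_normalization, assess,
                                      batch_classification_accuracy, fit_normae,
                                      load_model, normalize_median,
                                      normalize_tic, qc_nist_cv, save_model)
from metaboflow.simulate import SimulationConfig, simulate_study

FAST = NormAEConfig(epochs=320, warmup_epochs=120, eval_every=10, patience=50)


def _complete_table(rng, n_features=30, n_bio=20, n_qc=6, n_batches=2):
    cols = [f"b{i}" for i in range(n_bio)] + [f"q{i}" for i in range(n_qc)]
    types = ["bio"] * n_bio + ["QC_NIST"] * n_qc
    # round-robin so biological and QC injections land in every batch
    batches = np.arange(n_bio + n_qc) % n_batches
    M = rng.lognormal(12, 1, (n_features, n_bio + n_qc))
    feats = pd.DataFrame(
        {"rt_min": rng.uniform(1, 10, n_features),
         "mz": rng.uniform(100, 900, n_features),
         "annotation": None, "annotation_score": np.nan,
         "metabolite_class": None, "carbons": np.nan},
        index=[f"f{i}" for i in range(n_features)])
    meta = pd.DataFrame({"sample_type": types, "batch": batches,
                         "injection_index": np.arange(n_bio + n_qc),
                         "group": "g"}, index=cols)
    return FeatureTable("lc_polar", feats,
                        pd.DataFrame(M, index=feats.index, columns=cols), meta)


# ------------------------------------------------------- scaling baselines --
def test_tic_identical_columns_unchanged():
    rng = np.random.default_rng(0)
    t = _complete_table(rng, n_bio=4, n_qc=3)
    t.matrix = pd.concat([t.matrix.iloc[:, [0]]] * 7, axis=1)
    t.matrix.columns = t.sample_meta.index
    out = normalize_tic(t)
    pd.testing.assert_frame_equal(out.matrix, t.matrix)


def test_column_scaling_removes_multiplicative_factor_exactly():
    rng = np.random.default_rng(1)
    t = _complete_table(rng)
    factors = rng.uniform(0.5, 2.0, t.matrix.shape[1])
    scaled = t.copy()
    scaled.matrix = t.matrix * factors
    for op in (normalize_tic, normalize_median):
        a = op(t).matrix.to_numpy()
        b = op(scaled).matrix.to_numpy()
        # per-injection factors are removed exactly; only the overall
        # rescaling anchor (grand mean statistic) differs
        ratio = b / a
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-10)


def test_tic_equalizes_column_sums_and_median_equalizes_medians():
    rng = np.random.default_rng(2)
    t = _complete_table(rng)
    sums = normalize_tic(t).matrix.sum(axis=0)
    assert np.allclose(sums, sums.iloc[0])
    meds = normalize_median(t).matrix.median(axis=0)
    assert np.allclose(meds, meds.iloc[0])


def test_column_scaling_rejects_missing_or_nonpositive():
    rng = np.random.default_rng(3)
    t = _complete_table(rng)
    t.matrix.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="imputed"):
        normalize_tic(t)


# ------------------------------------------------------------ autoencoder --
@pytest.fixture(scope="module")
def batchy_table():
    """Small table with strong injected batch structure, fully imputed."""
    cfg = SimulationConfig(
        n_subjects=120, n_batches=3, seed=21, inter_batch_sd=0.6,
        n_features={"lc_polar": 60, "lc_lipid": 20, "gc": 10})
    *_, tables, truth = simulate_study(cfg)
    t = impute(coverage_filter(tables["lc_polar"], 0.5), lod=1e4, seed=2)
    return t, truth


def test_single_batch_rejected():
    rng = np.random.default_rng(4)
    t = _complete_table(rng, n_batches=1)
    with pytest.raises(ValueError, match="2 batches"):
        fit_normae(t, config=FAST, seed=0)


def test_fit_rejects_missing_cells():
    rng = np.random.default_rng(5)
    t = _complete_table(rng)
    t.matrix.iloc[2, 3] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit_normae(t, config=FAST, seed=0)


def test_same_seed_gives_identical_losses(batchy_table):
    t, _ = batchy_table
    cfg = NormAEConfig(epochs=60, warmup_epochs=20, eval_every=10, patience=50)
    a = fit_normae(t, config=cfg, seed=3)
    b = fit_normae(t, config=cfg, seed=3)
    assert np.allclose(a.history["loss"], b.history["loss"])
    corr_a = apply_normalization(a, t).matrix
    corr_b = apply_normalization(b, t).matrix
    pd.testing.assert_frame_equal(corr_a, corr_b)


def test_plain_autoencoder_beats_pca_bound(batchy_table):
    """λ=0 reduces to a plain autoencoder whose reconstruction error stays
    within 1.5× of a same-rank PCA."""
    from sklearn.decomposition import PCA

    t, _ = batchy_table
    cfg = NormAEConfig(lambda_batch=0.0, lambda_order=0.0, epochs=800,
                       warmup_epochs=800, eval_every=10, patience=10**6)
    model = fit_normae(t, config=cfg, seed=1)
    cols = t.columns_of_type("bio", "QC_bio", "QC_NIST")
    pos = t.matrix.columns.get_indexer(cols)
    X = np.log2(np.maximum(t.matrix.to_numpy(dtype=float).T, 1.0))[pos]
    Xs = (X - model.center) / model.scale
    # training-mode reconstruction (true batch conditioning)
    codes = pd.factorize(t.sample_meta.loc[cols, "batch"])[0]
    onehot = np.zeros((len(Xs), model.n_batches))
    onehot[np.arange(len(Xs)), codes] = 1.0
    Xhat = model.decode(model.encode(Xs), onehot, np.zeros((len(Xs), 1)))
    ae_mse = float(((Xhat - Xs) ** 2).mean())
    pca = PCA(n_components=model.config.latent_dim, random_state=0).fit(Xs)
    pca_mse = float(((pca.inverse_transform(pca.transform(Xs)) - Xs) ** 2).mean())
    assert ae_mse <= 1.5 * pca_mse


def test_adversary_reduces_batch_predictability(batchy_table):
    """Latent codes of the adversarial model predict batch worse than the
    raw data do."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import cross_val_score

    t, _ = batchy_table
    model = fit_normae(t, config=FAST, seed=2)
    cols = t.columns_of_type("bio", "QC_bio", "QC_NIST")
    pos = t.matrix.columns.get_indexer(cols)
    X = np.log2(np.maximum(t.matrix.to_numpy(dtype=float).T, 1.0))[pos]
    Xs = (X - model.center) / model.scale
    y = pd.factorize(t.sample_meta.loc[cols, "batch"])[0]
    Z = model.encode(Xs)

    def acc(features):
        clf = LogisticRegression(max_iter=2000)
        return float(cross_val_score(clf, features, y, cv=3).mean())

    assert acc(Z) <= acc(Xs)
    # the trained discriminator itself is also near or below its raw skill
    assert 0.0 <= batch_classification_accuracy(model, t) <= 1.0


def test_correction_reduces_qc_nist_cv(batchy_table):
    t, _ = batchy_table
    model = fit_normae(t, config=FAST, seed=0)
    corr = apply_normalization(model, t)
    assert qc_nist_cv(corr).median() < qc_nist_cv(t).median()


def test_apply_requires_matching_features(batchy_table):
    t, _ = batchy_table
    model = fit_normae(t, config=FAST, seed=0)
    other = t.subset_features(t.features.index[:-2])
    with pytest.raises(ValueError, match="feature set"):
        apply_normalization(model, other)


def test_zero_batch_effect_data_nearly_unchanged():
    cfg = SimulationConfig(
        n_subjects=80, n_batches=2, seed=31, inter_batch_sd=0.0,
        drift_slope_sd=0.0, noise_sd=0.15,
        n_features={"lc_polar": 40, "lc_lipid": 15, "gc": 10})
    *_, tables, _ = simulate_study(cfg)
    t = impute(coverage_filter(tables["lc_polar"], 0.5), lod=1e4, seed=2)
    model = fit_normae(t, config=FAST, seed=0)
    corr = apply_normalization(model, t)
    cols = t.columns_of_type("bio")
    rel = np.abs(np.log2(corr.matrix[cols] / t.matrix[cols]))
    # nothing to remove: reconstruction within a fraction of the noise level
    assert float(np.median(rel)) < 0.3


def test_second_application_changes_little(batchy_table):
    t, _ = batchy_table
    model = fit_normae(t, config=FAST, seed=0)
    once = apply_normalization(model, t)
    twice = apply_normalization(model, once)
    cols = t.columns_of_type("bio", "QC_NIST")
    first_change = np.abs(np.log2(once.matrix[cols] / t.matrix[cols]))
    second_change = np.abs(np.log2(twice.matrix[cols] / once.matrix[cols]))
    assert float(np.median(second_change)) < 0.5 * float(np.median(first_change))
    assert float(np.median(np.abs(twice.matrix[cols] / once.matrix[cols] - 1))) < 0.15


def test_checkpoint_roundtrip(batchy_table, tmp_path):
    t, _ = batchy_table
    model = fit_normae(t, config=FAST, seed=0)
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    assert back.n_batches == model.n_batches
    assert back.config == model.config
    a = apply_normalization(model, t).matrix
    b = apply_normalization(back, t).matrix
    pd.testing.assert_frame_equal(a, b)


def test_checkpoint_rejects_foreign_files(tmp_path):
    path = tmp_path / "junk.npz"
    np.savez_compressed(path, header=np.frombuffer(b'{"format": "x"}',
                                                   dtype=np.uint8))
    with pytest.raises(ValueError, match="checkpoint"):
        load_model(path)


# ---------------------------------------------------------------- assess ---
def test_assess_identity_gives_ratio_one(batchy_table):
    t, _ = batchy_table
    rep = assess(t, t)
    assert rep.qc_dispersion_ratio == pytest.approx(1.0)
    pd.testing.assert_series_equal(rep.cv_before, rep.cv_after)


def test_assess_detects_perfect_offset_removal():
    rng = np.random.default_rng(11)
    t = _complete_table(rng, n_features=40, n_bio=30, n_qc=8, n_batches=2)
    # make QC_NIST injections true replicates of one pooled metabolome
    nist_cols = t.columns_of_type("QC_NIST")
    base = rng.lognormal(12, 1, (40, 1))
    noise = rng.normal(1.0, 0.02, (40, len(nist_cols)))
    t.matrix[nist_cols] = base * noise
    clean = t.copy()
    dirty = t.copy()
    offsets = rng.normal(0, 1.0, (40, 1)) * \
        (t.sample_meta["batch"].to_numpy() == 1)
    dirty.matrix = clean.matrix * np.exp2(offsets)
    rep = assess(dirty, clean)
    assert rep.qc_dispersion_ratio < 0.5
    assert rep.cv_after.median() < rep.cv_before.median()


def test_assess_requires_three_qc_nist():
    rng = np.random.default_rng(12)
    t = _complete_table(rng, n_qc=2)
    with pytest.raises(ValueError, match="QC_NIST"):
        assess(t, t)


def test_assess_deterministic(batchy_table):
    t, _ = batchy_table
    model = fit_normae(t, config=FAST, seed=0)
    corr = apply_normalization(model, t)
    r1 = assess(t, corr)
    r2 = assess(t, corr)
    assert r1.qc_dispersion_ratio == r2.qc_dispersion_ratio
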