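"""Coverage filtering, imputation decision tree, annotation, deduplication."""

import numpy as np
import pandas as pd
import pytest

from metaboflow.containers import FeatureTable
from metaboflow.curation import (coverage_filter, deduplicate, impute,
                                 match_annotation)


def _table(rows, n_bio=10, n_qc=2, platform="lc_polar"):
    """rows: feature_id -> dict(values=list over bio cols (None=missing),
    annotation=..., rt=..., ...)"""
    bio_cols = [f"b{i}" for i in range(n_bio)]
    qc_cols = [f"q{i}" for i in range(n_qc)]
    feats, data = {}, {}
    for fid, spec in rows.items():
        vals = [np.nan if v is None else float(v) for v in spec["values"]]
        qc_vals = [np.nan if v is None else float(v)
                   for v in spec.get("qc", [np.nan] * n_qc)]
        data[fid] = vals + qc_vals
        feats[fid] = {
            "rt_min": spec.get("rt", 5.0), "mz": spec.get("mz", 300.0),
            "annotation": spec.get("annotation"),
            "annotation_score": spec.get("score", np.nan),
            "metabolite_class": spec.get("cls"),
            "carbons": spec.get("carbons", np.nan),
        }
    features = pd.DataFrame(feats).T
    matrix = pd.DataFrame(data).T
    matrix.columns = bio_cols + qc_cols
    meta = pd.DataFrame(
        {"sample_type": ["bio"] * n_bio + ["QC_NIST"] * n_qc,
         "batch": [0] * (n_bio // 2) + [1] * (n_bio - n_bio // 2) + [0, 1][:n_qc],
         "group": "g"},
        index=matrix.columns)
    return FeatureTable(platform, features.loc[matrix.index], matrix, meta)


# ---------------------------------------------------------------- coverage --
def test_low_coverage_unknown_removed_annotated_kept():
    t = _table({
        "unk_low": {"values": [100] * 4 + [None] * 6},   # 40% coverage
        "unk_ok": {"values": [100] * 6 + [None] * 4},    # 60%
        "ann_low": {"values": [100] * 1 + [None] * 9,    # 10% but annotated
                    "annotation": "MET_X"},
    })
    out = coverage_filter(t, 0.5)
    assert set(out.features.index) == {"unk_ok", "ann_low"}
    strict = coverage_filter(t, 0.5, drop_low_coverage_annotated=True)
    assert set(strict.features.index) == {"unk_ok"}


def test_threshold_zero_is_identity():
    t = _table({"a": {"values": [100] * 2 + [None] * 8}})
    assert coverage_filter(t, 0.0).features.index.equals(t.features.index)


def test_coverage_exactly_at_threshold_is_kept():
    t = _table({"a": {"values": [100] * 5 + [None] * 5}})  # exactly 50%
    assert "a" in coverage_filter(t, 0.5).features.index


# ---------------------------------------------------------------- impute ----
def _branch_table():
    return _table({
        # abundance 60%, median 2000
        "med": {"values": [2000] * 6 + [None] * 4, "qc": [None, 1.0]},
        # abundance 30%, mean 2e5 -> LOD branch
        "lod": {"values": [2e5] * 3 + [None] * 7},
        # abundance 30%, mean 5e4 -> zero branch
        "zero": {"values": [5e4] * 3 + [None] * 7},
    })


def test_imputation_branches():
    out = impute(_branch_table(), lod=500.0, seed=0)
    M = out.matrix
    assert not M.isna().any().any()
    med_imputed = M.loc["med", [f"b{i}" for i in range(6, 10)]]
    assert ((med_imputed >= 1900) & (med_imputed <= 2100)).all()
    lod_imputed = M.loc["lod", [f"b{i}" for i in range(3, 10)]]
    assert ((lod_imputed >= 475) & (lod_imputed <= 525)).all()
    assert (M.loc["zero", [f"b{i}" for i in range(3, 10)]] == 0).all()


def test_qc_missing_takes_batch_median_of_bio():
    out = impute(_branch_table(), lod=500.0, seed=0)
    # q0 is in batch 0 whose detected bio values for "med" are all 2000
    assert out.matrix.loc["med", "q0"] == pytest.approx(2000.0)
    # detected QC cells are untouched
    assert out.matrix.loc["med", "q1"] == pytest.approx(1.0)


def test_impute_deterministic_and_touches_only_missing():
    t = _branch_table()
    a = impute(t, lod=500.0, seed=3).matrix
    b = impute(t, lod=500.0, seed=3).matrix
    pd.testing.assert_frame_equal(a, b)
    c = impute(t, lod=500.0, seed=4).matrix
    present = t.matrix.notna()
    # detected cells are untouched by either seed
    pd.testing.assert_frame_equal(a.where(present), t.matrix.where(present))
    pd.testing.assert_frame_equal(c.where(present), t.matrix.where(present))
    # seeds differ only in the noise applied to imputed cells
    assert ((a != c) & ~present).to_numpy().sum() > 0


def test_imputed_cells_obey_branches_on_random_tables(random_table_factory):
    for i in range(300):
        rng = np.random.default_rng(i)
        t = random_table_factory(rng, n_features=int(rng.integers(3, 8)))
        lod = float(rng.uniform(100, 1e5))
        out = impute(t, lod=lod, seed=i)
        assert not out.matrix.isna().any().any()
        _assert_branches(t, out, lod)


def _assert_branches(before: FeatureTable, after: FeatureTable, lod: float):
    bio_cols = before.bio_columns
    bio = before.matrix[bio_cols]
    abundance = bio.notna().mean(axis=1)
    medians = bio.median(axis=1)
    means = bio.mean(axis=1)
    for f in before.matrix.index:
        for c in bio_cols:
            if pd.notna(before.matrix.at[f, c]):
                continue
            v = after.matrix.at[f, c]
            if abundance[f] > 0.5 and pd.notna(medians[f]):
                assert abs(v - medians[f]) <= 0.05 * medians[f] + 1e-9
            elif pd.notna(means[f]) and means[f] > 1e5:
                assert abs(v - lod) <= 0.05 * lod + 1e-9
            else:
                assert v == 0.0


def test_impute_rejects_bad_lod():
    with pytest.raises(ValueError):
        impute(_branch_table(), lod=0.0)


# ---------------------------------------------------------- annotation -----
def test_match_annotation_window_and_ordering():
    lib = pd.DataFrame({
        "name": ["A", "B", "C"],
        "rt": [5.10, 5.02, 5.25],
        "mz": [180.0634 * (1 + 7e-6), 180.0634 * (1 + 3e-6), 180.0634],
        "class": ["sugar", "sugar", "sugar"],
    })
    feat = {"rt_min": 5.00, "mz": 180.0634}
    assert match_annotation(feat, lib)["name"] == "B"  # 3 ppm beats 7 ppm
    none = match_annotation({"rt_min": 4.0, "mz": 180.0634}, lib)
    assert none is None


def test_match_annotation_equals_bruteforce_scan():
    rng = np.random.default_rng(9)
    for _ in range(200):
        lib = pd.DataFrame({
            "name": [f"L{i}" for i in range(20)],
            "rt": rng.uniform(4.5, 5.5, 20),
            "mz": 300.0 * (1 + rng.uniform(-3e-5, 3e-5, 20)),
        })
        feat = {"rt_min": 5.0, "mz": 300.0}
        got = match_annotation(feat, lib)
        cands = []
        for _, row in lib.iterrows():
            drt = abs(row["rt"] - feat["rt_min"])
            ppm = abs(row["mz"] - feat["mz"]) / row["mz"] * 1e6
            if drt <= 0.2 and ppm < 10.0:
                cands.append((ppm, drt, row["name"]))
        if not cands:
            assert got is None
        else:
            assert got["name"] == min(cands)[2]


# -------------------------------------------------------- deduplication ----
def _dedup_tables(polar_rows, gc_rows=None, lipid_rows=None):
    tables = {"lc_polar": _table(polar_rows, platform="lc_polar")}
    if gc_rows:
        tables["gc"] = _table(gc_rows, platform="gc")
    if lipid_rows:
        tables["lc_lipid"] = _table(lipid_rows, platform="lc_lipid")
    return {p: impute(t, lod=100.0, seed=0) for p, t in tables.items()}


def test_tca_metabolite_prefers_gc():
    tables = _dedup_tables(
        polar_rows={"p1": {"values": [5e5] * 8 + [None] * 2, "rt": 1.5,
                           "annotation": "alpha-KG", "cls": "tca_intermediate",
                           "score": 0.7}},
        gc_rows={"g1": {"values": [4e5] * 7 + [None] * 3, "rt": 12.0,
                        "annotation": "alpha-KG", "cls": "tca_intermediate",
                        "score": 0.9}})
    res = deduplicate(tables)
    kept = res.kept.set_index("annotation")
    assert kept.loc["alpha-KG", "platform"] == "gc"
    assert kept.loc["alpha-KG", "rule"] == "rule1_gc_class"
    assert (res.dropped["platform"] == "lc_polar").all()


def test_rt_window_prefers_polar_for_hydrocortisone_like_case():
    tables = _dedup_tables(
        polar_rows={"p1": {"values": [6e5] * 9 + [None], "rt": 2.8,
                           "annotation": "hydrocortisone", "cls": "steroid"}},
        lipid_rows={"l1": {"values": [3e5] * 5 + [None] * 5, "rt": 0.7,
                           "annotation": "hydrocortisone", "cls": "steroid"}})
    res = deduplicate(tables)
    kept = res.kept.set_index("annotation")
    assert kept.loc["hydrocortisone", "platform"] == "lc_polar"
    assert kept.loc["hydrocortisone", "rule"] == "rule3_rt_window"


def test_long_chain_fatty_acid_prefers_lipid_platform():
    tables = _dedup_tables(
        polar_rows={"p1": {"values": [6e5] * 9 + [None], "rt": 3.0,
                           "annotation": "FA 16:0", "cls": "fatty_acid",
                           "carbons": 16}},
        lipid_rows={"l1": {"values": [3e5] * 8 + [None] * 2, "rt": 8.0,
                           "annotation": "FA 16:0", "cls": "fatty_acid",
                           "carbons": 16}})
    res = deduplicate(tables)
    kept = res.kept.set_index("annotation")
    assert kept.loc["FA 16:0", "platform"] == "lc_lipid"
    assert kept.loc["FA 16:0", "rule"] == "rule2_long_chain_fa"


def test_single_platform_annotation_passes_through():
    tables = _dedup_tables(
        polar_rows={"p1": {"values": [6e5] * 10, "annotation": "unique_met"},
                    "p2": {"values": [1e5] * 10}})
    res = deduplicate(tables)
    assert res.dropped.empty
    assert set(res.kept["annotation"]) == {"unique_met"}
    assert res.merged.n_features == 2


def test_dedup_size_accounting_and_rule_ids():
    tables = _dedup_tables(
        polar_rows={"p1": {"values": [6e5] * 8 + [None] * 2, "rt": 5.0,
                           "annotation": "dup1", "score": 0.9},
                    "p2": {"values": [6e5] * 10, "rt": 6.0,
                           "annotation": "dup2", "score": 0.5}},
        lipid_rows={"l1": {"values": [3e5] * 6 + [None] * 4, "rt": 5.0,
                           "annotation": "dup1", "score": 0.4},
                    "l2": {"values": [3e5] * 10, "rt": 6.0,
                           "annotation": "dup2", "score": 0.8}})
    res = deduplicate(tables)
    total = sum(t.n_features for t in tables.values())
    assert res.merged.n_features == total - len(res.dropped)
    assert res.dropped["rule"].str.startswith("rule").all()
    # merged table never carries one annotation on two platforms
    ann = res.merged.features.dropna(subset=["annotation"])
    dup_check = ann.groupby("annotation")["platform"].nunique()
    assert (dup_check == 1).all()


def test_dedup_idempotent():
    tables = _dedup_tables(
        polar_rows={"p1": {"values": [6e5] * 8 + [None] * 2, "rt": 5.0,
                           "annotation": "dup1", "score": 0.9}},
        lipid_rows={"l1": {"values": [3e5] * 6 + [None] * 4, "rt": 5.0,
                           "annotation": "dup1", "score": 0.4}})
    once = deduplicate(tables)
    again = deduplicate({"merged": once.merged})
    assert again.dropped.empty
    assert again.merged.n_features == once.merged.n_features
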