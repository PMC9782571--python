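import numpy as np
import pandas as pd
import pytest

from metaboflow.containers import FeatureTable
from metaboflow.curation import coverage_filter, impute
from metaboflow.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """A moderate synthetic study shared by read-only tests."""
    cfg = SimulationConfig(
        n_subjects=120,
        n_batches=3,
        n_features={"lc_polar": 60, "lc_lipid": 60, "gc": 30},
        seed=42,
    )
    roster, eligible, sched, tables, truth = simulate_study(cfg)
    return {"config": cfg, "roster": roster, "eligible": eligible,
            "schedule": sched, "tables": tables, "truth": truth}


@pytest.fixture(scope="session")
def imputed_polar(study):
    cfg = study["config"]
    t = coverage_filter(study["tables"]["lc_polar"], 0.5)
    return impute(t, lod=cfg.lod_intensity["lc_polar"], seed=1)


def make_feature_table(rng, n_features=5, n_bio=8, n_qc=3, n_batches=2,
                       missing_rate=0.35, annotation=None):
    """Small random feature table with bio + QC_NIST injections."""
    cols = [f"b{i}" for i in range(n_bio)] + [f"q{i}" for i in range(n_qc)]
    types = ["bio"] * n_bio + ["QC_NIST"] * n_qc
    batches = (np.arange(n_bio + n_qc) * n_batches // (n_bio + n_qc))
    M = rng.lognormal(10, 2, (n_features, n_bio + n_qc))
    M[rng.random(M.shape) < missing_rate] = np.nan
    feats = pd.DataFrame(
        {"rt_min": rng.uniform(1, 10, n_features),
         "mz": rng.uniform(100, 500, n_features),
         "annotation": annotation, "annotation_score": np.nan,
         "metabolite_class": None, "carbons": np.nan},
        index=[f"f{i}" for i in range(n_features)])
    meta = pd.DataFrame(
        {"sample_type": types, "batch": batches,
         "group": ["g"] * (n_bio + n_qc)}, index=cols)
    return FeatureTable("lc_polar", feats,
                        pd.DataFrame(M, index=feats.index, columns=cols), meta)


@pytest.fixture
def random_table_factory():
    return make_feature_table
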