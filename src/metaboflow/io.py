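"""Readers and writers: TSV for tables, JSON for reports, YAML for config.

A feature table is stored as one TSV whose leading columns are feature
metadata (rt_min, mz, annotation, annotation_score, metabolite_class,
carbons, platform) followed by one intensity column per injection, plus a
companion sample sheet TSV describing the injections.  Every writer/reader
pair round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import FeatureTable
from .qc import StandardDef

FEATURE_META_COLS = ["rt_min", "mz", "annotation", "annotation_score",
                     "metabolite_class", "carbons", "coverage",
                     "mean_intensity"]
SAMPLE_META_COLS = ["sample_type", "batch", "injection_index",
                    "concentration", "group", "hospital", "sex", "age",
                    "subject_id"]


def write_feature_table(table: FeatureTable, path: Path,
                        sample_sheet: Path | None = None) -> None:
    path = Path(path)
    meta = table.features.reindex(columns=FEATURE_META_COLS)
    combined = pd.concat([meta, table.matrix], axis=1)
    combined.insert(0, "platform", table.platform)
    combined.to_csv(path, sep="\t", index_label="feature_id")
    if sample_sheet is not None:
        write_sample_sheet(table.sample_meta, sample_sheet)


def read_feature_table(path: Path, sample_sheet: Path) -> FeatureTable:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    platform = str(df["platform"].iloc[0])
    features = df[FEATURE_META_COLS].copy()
    features["annotation"] = features["annotation"].where(
        features["annotation"].notna(), None)
    features["metabolite_class"] = features["metabolite_class"].where(
        features["metabolite_class"].notna(), None)
    matrix = df.drop(columns=["platform", *FEATURE_META_COLS])
    meta = read_sample_sheet(sample_sheet)
    matrix.columns = matrix.columns.set_names(meta.index.name)
    return FeatureTable(platform=platform, features=features,
                        matrix=matrix, sample_meta=meta.loc[matrix.columns])


def write_sample_sheet(meta: pd.DataFrame, path: Path) -> None:
    meta.reindex(columns=[c for c in SAMPLE_META_COLS if c in meta.columns]) \
        .to_csv(path, sep="\t", index_label="sample_id")


def read_sample_sheet(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_schedule(entries: pd.DataFrame, path: Path) -> None:
    entries.to_csv(path, sep="\t", index=False)


def read_schedule(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_standards(standards: list[StandardDef], path: Path) -> None:
    rows = [{"name": s.name, "platform": s.platform,
             "expected_rt": s.expected_rt,
             "expected_mz": "" if s.expected_mz is None else s.expected_mz,
             "gradient": "" if not s.gradient_concentrations
             else ",".join(str(c) for c in s.gradient_concentrations)}
            for s in standards]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_standards(path: Path) -> list[StandardDef]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        mz = None if (pd.isna(row.expected_mz) or row.expected_mz == "") \
            else float(row.expected_mz)
        grad = None
        if isinstance(row.gradient, str) and row.gradient:
            grad = tuple(float(x) for x in row.gradient.split(","))
        out.append(StandardDef(name=row.name, platform=row.platform,
                               expected_rt=float(row.expected_rt),
                               expected_mz=mz, gradient_concentrations=grad))
    return out


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return None if not np.isfinite(o) else float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        return super().default(o)


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_Encoder,
                                     sort_keys=True) + "\n")


def read_json(path: Path):
    return json.loads(Path(path).read_text())


def write_yaml(obj: dict, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def read_yaml(path: Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
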