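"""Feature curation: coverage filtering, imputation, annotation, deduplication.

The imputation decision tree distinguishes sample type and feature abundance
(fraction of biological injections with a detected value): missing QC_bio and
QC_NIST cells take the batch median of the biological samples; a biological
cell of a feature with abundance above 50% takes the feature median with ±5%
uniform noise; below 50% abundance with mean intensity above 1E5 it takes the
platform limit of detection with ±5% noise; otherwise zero.

Deduplication resolves metabolites annotated on more than one platform with
an ordered rule cascade driven by physicochemical class, carbon count,
retention-time window [2, 14] min, and annotation/abundance/intensity
tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CurationResult, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "coverage_filter",
    "impute",
    "match_annotation",
    "annotate_table",
    "deduplicate",
    "GC_PREFERRED_CLASSES",
]

#: Classes for which the GC platform is preferred when detected on both
#: GC and LC (well-derivatizing small polar metabolites).
GC_PREFERRED_CLASSES = frozenset(
    {
        "sugar",
        "amino_acid",
        "hydroxy_short_chain_fatty_acid",
        "tca_intermediate",
        "urea",
        "uric_acid",
        "creatinine",
        "creatine",
    }
)

#: Preferred LC retention-time window (minutes) for rule 3.
RT_WINDOW = (2.0, 14.0)


def coverage_filter(
    table: FeatureTable,
    threshold: float = 0.5,
    drop_low_coverage_annotated: bool = False,
) -> FeatureTable:
    """Remove unknown features detected in fewer than ``threshold`` of
    biological injections.

    Annotated features are kept regardless of coverage by default; set
    ``drop_low_coverage_annotated`` to apply the cutoff to them too.
    ``threshold=0`` leaves the table unchanged.
    """
    if table.n_features == 0:
        raise ValueError("empty feature table")
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    cov = table.coverage()
    low = cov < threshold
    drop = low if drop_low_coverage_annotated else (low & ~table.is_annotated())
    kept = table.features.index[~drop]
    logger.info(
        "%s: coverage filter dropped %d of %d features",
        table.platform, int(drop.sum()), table.n_features,
    )
    return table.subset_features(kept)


#: Mean-intensity cutoff separating the LOD branch from the zero branch.
LOW_INTENSITY_CUTOFF = 1e5


def impute(table: FeatureTable, lod: float, seed: int = 0) -> FeatureTable:
    """Fill every missing cell according to the imputation decision tree.

    Deterministic given ``seed``; detected cells are never touched.  The ±5%
    noise is uniform.  A feature with no detected biological value cannot
    supply a median and falls through to the LOD/zero branch (logged).
    """
    if lod <= 0:
        raise ValueError("lod must be > 0")
    import warnings

    rng = np.random.default_rng(seed)
    out = table.copy()
    M = out.matrix.to_numpy(dtype=float)
    miss = np.isnan(M)
    types = table.sample_meta["sample_type"].to_numpy()
    batch_of = table.sample_meta["batch"].to_numpy()
    is_bio = types == "bio"
    is_qc = np.isin(types, ("QC_bio", "QC_NIST"))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        bio = M[:, is_bio]
        abundance = (~np.isnan(bio)).mean(axis=1) if is_bio.any() else \
            np.zeros(len(M))
        medians = np.nanmedian(bio, axis=1) if is_bio.any() else \
            np.full(len(M), np.nan)
        means = np.nanmean(bio, axis=1) if is_bio.any() else \
            np.full(len(M), np.nan)

        # biological cells: median / LOD / zero decision tree, ±5% noise
        rows, cols = np.nonzero(miss & is_bio[None, :])
        u = 1.0 + rng.uniform(-0.05, 0.05, size=len(rows))
        vals = np.zeros(len(rows))
        med_branch = (abundance[rows] > 0.5) & np.isfinite(medians[rows])
        vals[med_branch] = medians[rows[med_branch]] * u[med_branch]
        lod_branch = (~med_branch & np.isfinite(means[rows])
                      & (means[rows] > LOW_INTENSITY_CUTOFF))
        vals[lod_branch] = lod * u[lod_branch]
        M[rows, cols] = vals
        n_fallthrough = int((abundance[rows] > 0.5).sum() - med_branch.sum())
        if n_fallthrough:
            logger.info("%d cells lacked a biological median; fell through "
                        "to the LOD/zero branch", n_fallthrough)

        # QC_bio / QC_NIST cells: batch median of the detected biological
        # values, falling back to the overall median, then 0
        for b in np.unique(batch_of[is_qc]):
            in_batch = is_bio & (batch_of == b)
            bmed = (np.nanmedian(bio[:, batch_of[is_bio] == b], axis=1)
                    if in_batch.any() else np.full(len(M), np.nan))
            bmed = np.where(np.isfinite(bmed), bmed, medians)
            bmed = np.where(np.isfinite(bmed), bmed, 0.0)
            qc_cols = np.nonzero(is_qc & (batch_of == b))[0]
            for c in qc_cols:
                M[miss[:, c], c] = bmed[miss[:, c]]

    # solvent blanks / standards mixtures carry no biology
    other = ~is_bio & ~is_qc
    M[miss & other[None, :]] = 0.0

    out.matrix = pd.DataFrame(M, index=out.matrix.index,
                              columns=out.matrix.columns)
    # preserve detection-based statistics: once every cell is filled,
    # coverage/abundance can no longer be recomputed from the matrix
    out.features["coverage"] = abundance
    out.features["mean_intensity"] = means
    logger.info("%s: imputed %d cells", table.platform, int(miss.sum()))
    return out


def match_annotation(feature, library: pd.DataFrame):
    """Best library match for a feature, or None.

    ``feature`` supplies ``rt_min`` and ``mz``; candidates are library rows
    with |ΔRT| ≤ 0.2 min and |Δm/z| < 10 ppm; the smallest ppm error wins,
    ties broken by smallest |ΔRT|.
    """
    drt = (library["rt"] - feature["rt_min"]).abs()
    ppm = (library["mz"] - feature["mz"]).abs() / library["mz"] * 1e6
    cand = library[(drt <= 0.2) & (ppm < 10.0)]
    if cand.empty:
        return None
    order = pd.DataFrame({"ppm": ppm[cand.index], "drt": drt[cand.index]})
    best = order.sort_values(["ppm", "drt"], kind="stable").index[0]
    return library.loc[best]


def annotate_table(table: FeatureTable, library: pd.DataFrame) -> FeatureTable:
    """Annotate every feature against a reference library in place of the
    existing annotation columns."""
    out = table.copy()
    for fid, row in out.features.iterrows():
        hit = match_annotation(row, library)
        if hit is not None:
            out.features.at[fid, "annotation"] = hit["name"]
            if "class" in hit:
                out.features.at[fid, "metabolite_class"] = hit["class"]
            if "carbons" in hit:
                out.features.at[fid, "carbons"] = hit["carbons"]
    return out


def _norm_class(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower().replace(" ", "_").replace("-", "_")
    return s or None


@dataclass
class _Candidate:
    platform: str
    feature_id: str
    rt: float
    metabolite_class: str | None
    carbons: float
    score: float
    abundance: float
    mean_intensity: float
    p_value: float
    log2fc: float


def _resolve(cands: list[_Candidate]) -> tuple[_Candidate, str]:
    """Apply the ordered precedence rules to one duplicated annotation."""
    classes = {c.metabolite_class for c in cands if c.metabolite_class}
    # rule 1: GC preferred for well-derivatizing polar classes
    if any(cl in GC_PREFERRED_CLASSES for cl in classes):
        gc = [c for c in cands if c.platform == "gc"]
        if gc:
            return gc[0], "rule1_gc_class"
    elif any(c.metabolite_class is None for c in cands) and any(
        c.platform == "gc" for c in cands
    ):
        logger.info("metabolite_class missing; GC-preference rule skipped")
    # rule 2: long-chain fatty acids (> 10 carbons) go to the lipid platform
    if any(cl and "fatty_acid" in cl for cl in classes):
        long_fa = [
            c for c in cands
            if c.metabolite_class and "fatty_acid" in c.metabolite_class
            and np.isfinite(c.carbons) and c.carbons > 10
        ]
        if long_fa and any(c.platform == "lc_lipid" for c in cands):
            lip = [c for c in cands if c.platform == "lc_lipid"]
            return lip[0], "rule2_long_chain_fa"
    # rule 3: between the LC platforms, prefer RT inside the window
    lc = [c for c in cands if c.platform in ("lc_polar", "lc_lipid")]
    if len(lc) >= 2:
        inside = [c for c in lc if RT_WINDOW[0] <= c.rt <= RT_WINDOW[1]]
        if 0 < len(inside) < len(lc):
            cands = inside + [c for c in cands if c.platform == "gc"]
            if len(cands) == 1:
                return cands[0], "rule3_rt_window"
    # rule 3b (optional): platform with the more significant contrast
    ps = [c.p_value for c in cands]
    if all(np.isfinite(p) for p in ps) and len(set(ps)) > 1:
        best = min(cands, key=lambda c: (c.p_value, -abs(c.log2fc)))
        return best, "rule3b_significance"
    # rule 4: annotation score, then abundance, then mean intensity
    def key(c: _Candidate):
        return (
            -(c.score if np.isfinite(c.score) else -np.inf),
            -(c.abundance if np.isfinite(c.abundance) else -np.inf),
            -(c.mean_intensity if np.isfinite(c.mean_intensity) else -np.inf),
            c.platform,
        )
    ranked = sorted(cands, key=key)
    top = ranked[0]
    if np.isfinite(top.score) and (
        len(ranked) == 1 or top.score != ranked[1].score
    ):
        return top, "rule4_score"
    if top.abundance != ranked[1].abundance:
        return top, "rule4_abundance"
    if top.mean_intensity != ranked[1].mean_intensity:
        return top, "rule4_intensity"
    return top, "rule4_platform_order"


def deduplicate(
    tables: dict[str, FeatureTable],
    contrast: dict[str, pd.DataFrame] | None = None,
) -> CurationResult:
    """Merge platforms and resolve annotations detected on more than one.

    ``contrast``, when given, maps platform → DataFrame indexed by feature_id
    with columns ``log2fc`` and ``p_value``; it enables the optional
    significance rule for duplicates the physicochemical rules cannot split.
    Unannotated features and single-platform annotations pass through
    unchanged.  Output row ids are ``platform:feature_id``.
    """
    ann_map: dict[str, list[_Candidate]] = {}
    for platform, table in tables.items():
        # prefer detection-based statistics recorded before imputation
        if "coverage" in table.features.columns:
            cov = table.features["coverage"]
        else:
            cov = table.coverage()
        if "mean_intensity" in table.features.columns:
            means = table.features["mean_intensity"]
        else:
            means = table.matrix[table.bio_columns].mean(axis=1)
        con = contrast.get(platform) if contrast else None
        for fid in table.features.index[table.is_annotated()]:
            row = table.features.loc[fid]
            p = lfc = np.nan
            if con is not None and fid in con.index:
                p = float(con.at[fid, "p_value"])
                lfc = float(con.at[fid, "log2fc"])
            ann_map.setdefault(str(row["annotation"]), []).append(
                _Candidate(
                    platform=platform,
                    feature_id=fid,
                    rt=float(row["rt_min"]),
                    metabolite_class=_norm_class(row.get("metabolite_class")),
                    carbons=float(row.get("carbons", np.nan)),
                    score=float(row.get("annotation_score", np.nan)),
                    abundance=float(cov[fid]),
                    mean_intensity=float(means[fid]),
                    p_value=p,
                    log2fc=lfc,
                )
            )

    kept_rows, dropped_rows = [], []
    losers: dict[str, set[str]] = {p: set() for p in tables}
    for annotation, cands in ann_map.items():
        if len(cands) == 1:
            kept_rows.append(
                {"feature_id": cands[0].feature_id, "platform": cands[0].platform,
                 "annotation": annotation, "rule": "unique"}
            )
            continue
        winner, rule = _resolve(cands)
        kept_rows.append(
            {"feature_id": winner.feature_id, "platform": winner.platform,
             "annotation": annotation, "rule": rule}
        )
        for c in cands:
            if c is not winner:
                losers[c.platform].add(c.feature_id)
                dropped_rows.append(
                    {"annotation": annotation, "platform": c.platform,
                     "feature_id": c.feature_id, "rule": rule}
                )

    common = None
    for table in tables.values():
        cols = table.matrix.columns
        common = cols if common is None else common.intersection(cols)
    feat_frames, mat_frames, meta = [], [], None
    for platform, table in tables.items():
        keep = table.features.index.difference(losers[platform], sort=False)
        feats = table.features.loc[keep].copy()
        mat = table.matrix.loc[keep, common]
        prefix = [f"{platform}:{fid}" for fid in keep]
        feats.index = prefix
        mat.index = prefix
        feats["platform"] = platform
        feat_frames.append(feats)
        mat_frames.append(mat)
        if meta is None:
            meta = table.sample_meta.loc[common]
    merged = FeatureTable(
        platform="merged",
        features=pd.concat(feat_frames),
        matrix=pd.concat(mat_frames),
        sample_meta=meta,
    )
    return CurationResult(
        merged=merged,
        kept=pd.DataFrame(kept_rows),
        dropped=pd.DataFrame(
            dropped_rows, columns=["annotation", "platform", "feature_id", "rule"]
        ),
    )
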