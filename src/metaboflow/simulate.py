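"""Synthetic clinical-metabolomics cohort generator.

Emulates a multi-centre plasma cohort measured on three MS platforms
(LC-MS polar, LC-MS lipid, GC-MS) with known ground truth, so every
downstream stage — screening, scheduling, QC metrics, curation,
batch-effect correction, differential analysis, classification — can be
exercised and validated without external data.

The intensity model is log-normal: on the log2 scale each cell is

    baseline(feature) + group_effect + batch_offset(batch, feature)
    + drift_slope(batch) × injection_position + N(0, noise_sd)

Group effects apply only to the configured informative features in case
samples.  QC_NIST injections share one fixed metabolome, so their replicate
spread isolates the technical terms; QC_bio is the mean metabolome of a
random 50% subject subset; QC_mix carries spiked standards on a
concentration gradient; QC_blank carries only noise near the limit of
detection.  Missingness is a floor rate plus a logistic function of how far
a cell's intensity falls below the platform LOD, so low-abundance features
go missing preferentially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PLATFORMS, FeatureTable
from .qc import StandardDef
from .scheduling import DEFAULT_GRADIENT, InjectionSchedule, interleave_qc, randomize_order
from .screening import SAMPLE_QUALITY_REASONS, SubjectRecord, screen_subject

__all__ = ["SimulationConfig", "GroundTruth", "simulate_roster",
           "simulate_feature_tables", "simulate_study"]

_CLASS_POOL = (
    ("sugar", np.nan), ("amino_acid", np.nan), ("tca_intermediate", np.nan),
    ("fatty_acid", 16.0), ("fatty_acid", 18.0), ("fatty_acid", 8.0),
    ("steroid", np.nan), ("nucleotide", np.nan), ("creatinine", np.nan),
    ("phospholipid", np.nan),
)


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters of the simulated cohort."""

    n_subjects: int = 200
    group_fractions: dict = field(default_factory=lambda: {
        "HCtrl": 0.10, "NC": 0.34, "LC": 0.23, "GC": 0.21, "CRC": 0.12})
    hospital_fractions: dict = field(default_factory=lambda: {
        "NCH": 0.68, "XYH": 0.27, "TJH": 0.05})
    female_fraction: float = 0.40
    age_mean: float = 57.0
    age_sd: float = 13.0
    batch_size: int = 40
    n_batches: int | None = None  # ceil(n_bio / batch_size) when None
    qc_period: int = 10
    gradient: tuple = DEFAULT_GRADIENT
    inter_batch_sd: float = 0.5       # log2 sd of batch offsets
    drift_slope_sd: float = 0.005     # log2 per injection position
    noise_sd: float = 0.2             # log2 residual sd
    missing_base_rate: float = 0.02
    lod_intensity: dict = field(default_factory=lambda: {
        "lc_polar": 1e4, "lc_lipid": 1e4, "gc": 1e3})
    n_features: dict = field(default_factory=lambda: {
        "lc_polar": 150, "lc_lipid": 150, "gc": 40})
    annotated_fraction: dict = field(default_factory=lambda: {
        "lc_polar": 0.15, "lc_lipid": 0.15, "gc": 1.0})
    n_duplicate_annotations: int = 8
    n_standards: int = 4
    n_informative: int = 20
    effect_log2fc: float = 1.0
    case_groups: tuple = ("LC", "GC", "CRC")
    baseline_log2_mean: float = 17.0
    baseline_log2_sd: float = 1.5
    violations: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (("group_fractions", self.group_fractions),
                           ("hospital_fractions", self.hospital_fractions)):
            total = sum(frac.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {total})")
            if any(v < 0 for v in frac.values()):
                raise ValueError(f"{name} must be non-negative")
        if self.n_subjects <= 0 or self.batch_size <= 0:
            raise ValueError("counts must be > 0")
        for sd in (self.inter_batch_sd, self.drift_slope_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.missing_base_rate <= 1:
            raise ValueError("missing_base_rate must be a probability")
        if sum(self.violations.values()) > self.n_subjects:
            raise ValueError("more violations than subjects")


@dataclass
class GroundTruth:
    """Everything the generator injected, for downstream validation."""

    batch_offsets: dict       # platform -> DataFrame (batch × feature), log2
    drift_slopes: dict        # platform -> Series batch -> slope
    informative_features: set
    true_log2fc: dict         # feature id -> injected log2 fold change
    true_missing_mask: dict   # platform -> DataFrame bool (feature × injection)
    standards: dict           # platform -> list[StandardDef]
    qc_observations: dict     # platform -> per-injection standard observations
    nist_level: dict          # platform -> Series feature -> log2 level


_VIOLATION_KEYS = ("age_under_18", "repeat_enrollment",
                   "unconfirmed_diagnosis", "failed_sample_quality")


def simulate_roster(config: SimulationConfig) -> list[SubjectRecord]:
    """Generate a consenting-subject roster, deterministic given the seed.

    ``config.violations`` maps violation kind (age_under_18,
    repeat_enrollment, unconfirmed_diagnosis, failed_sample_quality) to the
    exact number of records that will fail screening for that reason; each
    violating record fires exactly one rule.
    """
    unknown = set(config.violations) - set(_VIOLATION_KEYS)
    if unknown:
        raise ValueError(f"unknown violation kinds: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    groups = rng.choice(list(config.group_fractions),
                        p=list(config.group_fractions.values()), size=n)
    hospitals = rng.choice(list(config.hospital_fractions),
                           p=list(config.hospital_fractions.values()), size=n)
    sexes = np.where(rng.random(n) < config.female_fraction, "female", "male")
    ages = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18.0, 90.0)

    roster = []
    for i in range(n):
        g = str(groups[i])
        claimed = ("healthy" if g == "HCtrl"
                   else "non_cancer" if g == "NC" else "cancer")
        roster.append(SubjectRecord(
            subject_id=f"S{i + 1:05d}",
            age=float(np.round(ages[i], 1)),
            group_claimed=claimed,
            process_time=float(np.round(rng.uniform(20, 200), 1)),
            volume=float(np.round(rng.uniform(80, 120), 1)),
            hospital=str(hospitals[i]),
            sex=str(sexes[i]),
            group=g,
        ))

    total_bad = sum(config.violations.values())
    if total_bad:
        bad_idx = rng.choice(n, size=total_bad, replace=False)
        pos = 0
        quality_cycle = 0
        for kind in _VIOLATION_KEYS:
            for _ in range(config.violations.get(kind, 0)):
                rec = roster[int(bad_idx[pos])]
                pos += 1
                if kind == "age_under_18":
                    rec.age = float(np.round(rng.uniform(8, 17.9), 1))
                elif kind == "repeat_enrollment":
                    rec.enrollment_count = 2
                elif kind == "unconfirmed_diagnosis":
                    rec.diagnosis_confirmed = False
                else:  # failed_sample_quality: rotate through the log fields
                    q = SAMPLE_QUALITY_REASONS[
                        quality_cycle % len(SAMPLE_QUALITY_REASONS)]
                    quality_cycle += 1
                    if q == "hemolysis":
                        rec.hemolysis = True
                    elif q == "discoloration":
                        rec.discoloration = True
                    elif q == "process_time_over_4h":
                        rec.process_time = float(np.round(rng.uniform(250, 420), 1))
                    elif q == "insufficient_volume":
                        rec.volume = float(np.round(rng.uniform(20, 59), 1))
                    else:
                        rec.improper_storage = True
    return roster


def _feature_metadata(config: SimulationConfig, platform: str,
                      rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_features[platform]
    if n <= config.n_standards:
        raise ValueError("n_features must exceed n_standards")
    rt_lo, rt_hi = (5.0, 38.0) if platform == "gc" else (0.3, 16.0)
    mz_lo, mz_hi = (70.0, 600.0) if platform == "gc" else (80.0, 1100.0)
    fids = [f"{platform}_F{i + 1:04d}" for i in range(n)]
    feats = pd.DataFrame(
        {
            "rt_min": np.round(rng.uniform(rt_lo, rt_hi, n), 3),
            "mz": np.round(rng.uniform(mz_lo, mz_hi, n), 4),
            "annotation": [None] * n,
            "annotation_score": np.nan,
            "metabolite_class": [None] * n,
            "carbons": np.nan,
            "is_standard": False,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    n_ann = int(round(config.annotated_fraction[platform] * n))
    ann_idx = feats.index[config.n_standards:config.n_standards + n_ann]
    for k, fid in enumerate(ann_idx):
        feats.at[fid, "annotation"] = f"MET_{platform}_{k + 1:03d}"
        feats.at[fid, "annotation_score"] = float(np.round(rng.uniform(0.5, 1.0), 3))
        cls, carb = _CLASS_POOL[int(rng.integers(len(_CLASS_POOL)))]
        feats.at[fid, "metabolite_class"] = cls
        feats.at[fid, "carbons"] = carb
    feats.iloc[:config.n_standards, feats.columns.get_loc("is_standard")] = True
    return feats


def _inject_duplicates(config: SimulationConfig,
                       feats: dict[str, pd.DataFrame],
                       rng: np.random.Generator) -> None:
    """Give ``n_duplicate_annotations`` metabolites a presence on 2 platforms."""
    pairs = [("lc_polar", "gc"), ("lc_polar", "lc_lipid"), ("lc_lipid", "gc")]
    for d in range(config.n_duplicate_annotations):
        p1, p2 = pairs[d % len(pairs)]
        cls, carb = _CLASS_POOL[int(rng.integers(len(_CLASS_POOL)))]
        name = f"DUP_{d + 1:03d}"
        for p in (p1, p2):
            ann = feats[p]["annotation"]
            pool = feats[p].index[ann.notna() & ~ann.astype(str).str.startswith("DUP_")]
            if len(pool) == 0:
                continue
            fid = pool[int(rng.integers(len(pool)))]
            feats[p].at[fid, "annotation"] = name
            feats[p].at[fid, "metabolite_class"] = cls
            feats[p].at[fid, "carbons"] = carb


def simulate_feature_tables(
    config: SimulationConfig,
    schedule: InjectionSchedule,
    roster: list[SubjectRecord],
) -> tuple[dict[str, FeatureTable], GroundTruth]:
    """Generate the three platform feature tables for a QC-interleaved schedule.

    ``roster`` supplies group/hospital/sex/age for the biological sample ids
    in ``schedule`` (one plasma sample per eligible subject).  Returns the
    platform tables and the injected ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    by_id = {r.subject_id: r for r in roster}
    entries = schedule.entries
    bio_ids = entries.loc[entries["sample_type"] == "bio", "sample_id"]
    missing_subj = [s for s in bio_ids if s not in by_id]
    if missing_subj:
        raise ValueError(f"schedule samples absent from roster: {missing_subj[:5]}")

    feats = {p: _feature_metadata(config, p, rng) for p in PLATFORMS}
    _inject_duplicates(config, feats, rng)

    all_fids = np.concatenate([f.index.to_numpy() for f in feats.values()])
    eligible_fids = np.concatenate([
        f.index[~f["is_standard"]].to_numpy() for f in feats.values()])
    n_inf = min(config.n_informative, len(eligible_fids))
    informative = set(rng.choice(eligible_fids, size=n_inf, replace=False).tolist())
    true_lfc = {fid: (config.effect_log2fc if fid in informative else 0.0)
                for fid in all_fids}

    # QC_bio pool: a random 50% of scheduled subjects
    subj_ids = list(dict.fromkeys(bio_ids))
    pool_ids = set(rng.choice(subj_ids, size=max(1, len(subj_ids) // 2),
                              replace=False).tolist())

    # per-injection design vectors
    n_inj = len(entries)
    types = entries["sample_type"].to_numpy()
    batches = entries["batch"].to_numpy()
    pos_in_batch = entries.groupby("batch").cumcount().to_numpy()
    concs = (entries["concentration"].to_numpy(dtype=float)
             if "concentration" in entries else np.full(n_inj, np.nan))
    is_case = np.array([
        (types[i] == "bio" and by_id[entries["sample_id"].iat[i]].group
         in config.case_groups) for i in range(n_inj)])
    in_pool_weight = np.array([
        1.0 if (s in pool_ids) else 0.0 for s in bio_ids])

    n_batches = int(batches.max()) + 1
    tables: dict[str, FeatureTable] = {}
    offsets, slopes, masks, registry, qc_obs, nist_levels = {}, {}, {}, {}, {}, {}

    sample_meta_base = pd.DataFrame({
        "sample_id": entries["sample_id"].to_numpy(),
        "sample_type": types,
        "batch": batches,
        "injection_index": entries["injection_index"].to_numpy(),
        "concentration": concs,
    }).set_index("sample_id")
    subj_cols = {}
    for col, get in (("group", lambda r: r.group), ("hospital", lambda r: r.hospital),
                     ("sex", lambda r: r.sex), ("age", lambda r: r.age),
                     ("subject_id", lambda r: r.subject_id)):
        subj_cols[col] = [
            get(by_id[s]) if s in by_id else ("" if col != "age" else np.nan)
            for s in sample_meta_base.index]
    for col, vals in subj_cols.items():
        sample_meta_base[col] = vals

    for platform in PLATFORMS:
        fmeta = feats[platform]
        nf = len(fmeta)
        fids = fmeta.index
        lod = config.lod_intensity[platform]
        log2_lod = np.log2(lod)

        baseline = rng.normal(config.baseline_log2_mean,
                              config.baseline_log2_sd, nf)
        lfc = np.array([true_lfc[f] for f in fids])
        nist_delta = rng.normal(0.0, 0.5, nf)
        nist = baseline + nist_delta
        blank_level = log2_lod - 1.0

        # QC_bio pool level: linear-scale mean over the pooled subjects
        case_subj = np.array([by_id[s].group in config.case_groups
                              for s in subj_ids])
        w = np.array([1.0 if s in pool_ids else 0.0 for s in subj_ids])
        w = w / w.sum()
        lin = (np.exp2(baseline[:, None] + np.outer(lfc, case_subj)) * w[None, :])
        pool_level = np.log2(lin.sum(axis=1))

        std_mask = fmeta["is_standard"].to_numpy()
        # response factor: standards hit ~baseline intensity at 20 µg/mL
        log2_resp = rng.normal(config.baseline_log2_mean, 0.5, nf) - np.log2(20.0)

        O = rng.normal(0.0, config.inter_batch_sd, (n_batches, nf))
        slope = rng.normal(0.0, config.drift_slope_sd, n_batches)

        L = np.empty((nf, n_inj))
        bio_mask = types == "bio"
        L[:, bio_mask] = (baseline[:, None]
                          + np.outer(lfc, is_case[bio_mask].astype(float)))
        L[:, types == "QC_NIST"] = nist[:, None]
        L[:, types == "QC_bio"] = pool_level[:, None]
        L[:, types == "QC_blank"] = blank_level
        mix = types == "QC_mix"
        if mix.any():
            mix_levels = np.full((nf, int(mix.sum())), blank_level)
            cvals = concs[mix]
            mix_levels[std_mask, :] = (log2_resp[std_mask, None]
                                       + np.log2(cvals)[None, :])
            L[:, mix] = mix_levels

        L = L + O[batches, :].T
        L = L + (slope[batches] * pos_in_batch)[None, :]
        if config.noise_sd > 0:
            L = L + rng.normal(0.0, config.noise_sd, L.shape)

        intensity = np.exp2(L)
        # missingness: floor rate plus logistic rise below the LOD
        p_miss = (config.missing_base_rate
                  + (1 - config.missing_base_rate)
                  / (1.0 + np.exp(-(log2_lod - L) / 1.0)))
        miss = rng.random(L.shape) < p_miss
        intensity[miss] = np.nan

        matrix = pd.DataFrame(intensity, index=fids,
                              columns=sample_meta_base.index)
        tables[platform] = FeatureTable(
            platform=platform,
            features=fmeta.drop(columns=["is_standard"]).copy(),
            matrix=matrix,
            sample_meta=sample_meta_base.copy(),
        )
        offsets[platform] = pd.DataFrame(O, columns=fids)
        offsets[platform].index.name = "batch"
        slopes[platform] = pd.Series(slope, name="drift_slope")
        masks[platform] = pd.DataFrame(miss, index=fids,
                                       columns=sample_meta_base.index)
        nist_levels[platform] = pd.Series(nist, index=fids)

        # standards registry + per-injection QC_mix observations
        stds = []
        rows = []
        rt_batch_shift = rng.normal(0.0, 0.05, n_batches)
        for si, fid in enumerate(fids[std_mask]):
            exp_rt = float(fmeta.at[fid, "rt_min"])
            exp_mz = (None if platform == "gc" else float(fmeta.at[fid, "mz"]))
            stds.append(StandardDef(
                name=f"STD_{platform}_{si + 1}", platform=platform,
                expected_rt=exp_rt, expected_mz=exp_mz,
                gradient_concentrations=tuple(config.gradient)))
            mix_idx = np.flatnonzero(mix)
            obs_rt = (exp_rt + rt_batch_shift[batches[mix_idx]]
                      + rng.normal(0, 0.02, len(mix_idx)))
            ppm_sd = {"lc_polar": 2.0, "lc_lipid": 1.0, "gc": 0.0}[platform]
            obs_mz = (np.nan if exp_mz is None
                      else exp_mz * (1 + rng.normal(0, ppm_sd, len(mix_idx)) * 1e-6))
            inten = intensity[fmeta.index.get_loc(fid), mix_idx]
            for k, j in enumerate(mix_idx):
                rows.append({
                    "standard": stds[-1].name, "batch": int(batches[j]),
                    "injection_index": int(entries["injection_index"].iat[j]),
                    "concentration": float(concs[j]),
                    "observed_rt": float(obs_rt[k]),
                    "observed_mz": (np.nan if exp_mz is None else float(obs_mz[k])),
                    "intensity": float(inten[k]) if np.isfinite(inten[k]) else np.nan,
                })
        registry[platform] = stds
        obs = pd.DataFrame(rows)
        qc_obs[platform] = obs.dropna(subset=["intensity"]) if len(rows) else obs

    truth = GroundTruth(
        batch_offsets=offsets, drift_slopes=slopes,
        informative_features=informative, true_log2fc=true_lfc,
        true_missing_mask=masks, standards=registry,
        qc_observations=qc_obs, nist_level=nist_levels,
    )
    return tables, truth


def simulate_study(config: SimulationConfig):
    """Roster → screening → schedule → tables, in one call.

    Returns ``(roster, eligible, schedule, tables, truth)`` where
    ``schedule`` is QC-interleaved and covers one plasma sample per eligible
    subject.
    """
    roster = simulate_roster(config)
    eligible = [r for r in roster if screen_subject(r)[0]]
    samples = pd.DataFrame({
        "sample_id": [r.subject_id for r in eligible],
        "hospital": [r.hospital for r in eligible],
        "group": [r.group for r in eligible],
        "sex": [r.sex for r in eligible],
        "age": [r.age for r in eligible],
    })
    sched = randomize_order(samples, batch_size=config.batch_size,
                            seed=config.seed, n_batches=config.n_batches)
    sched = interleave_qc(sched, qc_period=config.qc_period,
                          gradient=config.gradient)
    tables, truth = simulate_feature_tables(config, sched, roster)
    return roster, eligible, sched, tables, truth
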