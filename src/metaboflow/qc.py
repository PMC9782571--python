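"""MS quality-control metrics on chemical standards.

Per-standard, per-batch retention-time deviation (observed − expected,
minutes), mass error (signed ppm), intensity coefficient of variation
(intra-batch over replicate injections, extra-batch over batch means), and
calibration linearity over the standards-mixture gradient.  Pass/fail bounds
default to what a stable large-batch acquisition is expected to hold
(|RT_dev| ≤ 0.3 min, mass error < 10 ppm on the polar LC platform and
< 5 ppm on the lipid platform, extra-batch Int_CV < 30%) and are
config-overridable; GC-MS runs in nominal-mass mode, so its reports carry no
mass-error metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardDef",
    "QCThresholds",
    "QCReport",
    "rt_deviation",
    "mass_error_ppm",
    "intensity_cv",
    "calibration_fit",
    "qc_report",
    "match_standard_feature",
]


@dataclass
class StandardDef:
    """A registered chemical standard (QC_mix component or FAME marker)."""

    name: str
    platform: str  # lc_polar | lc_lipid | gc
    expected_rt: float  # minutes
    expected_mz: float | None = None  # absent for GC nominal-mass mode
    gradient_concentrations: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.expected_rt <= 0:
            raise ValueError("expected_rt must be > 0")
        if self.expected_mz is not None and self.expected_mz <= 0:
            raise ValueError("expected_mz must be > 0 when present")


@dataclass
class QCThresholds:
    rt_dev_abs_max: float = 0.3  # minutes
    mass_err_ppm_max: dict = field(
        default_factory=lambda: {"lc_polar": 10.0, "lc_lipid": 5.0}
    )
    int_cv_extra_max: float = 30.0  # percent
    calibration_r2_min: float = 0.90


@dataclass
class QCReport:
    """Per-standard/per-batch metric table plus per-standard flags."""

    per_batch: pd.DataFrame  # standard, batch, rt_dev_mean, mass_err_mean, int_cv_intra
    per_standard: pd.DataFrame  # standard, int_cv_extra, calibration_r2, ...
    flags: dict[str, dict[str, bool]]

    def passed(self) -> bool:
        return all(all(v.values()) for v in self.flags.values())

    def to_dict(self) -> dict:
        return {
            "per_batch": self.per_batch.to_dict(orient="records"),
            "per_standard": self.per_standard.to_dict(orient="records"),
            "flags": self.flags,
        }


def rt_deviation(observed_rt: float, expected_rt: float):
    """Signed retention-time deviation, observed minus expected (minutes)."""
    observed_rt = np.asarray(observed_rt, dtype=float)
    if not (np.all(np.isfinite(observed_rt)) and np.isfinite(expected_rt)):
        raise ValueError("retention times must be finite")
    return observed_rt - expected_rt


def mass_error_ppm(observed_mz: float, expected_mz: float):
    """Signed relative m/z error in parts per million."""
    if expected_mz <= 0:
        raise ValueError("expected_mz must be > 0")
    observed_mz = np.asarray(observed_mz, dtype=float)
    return (observed_mz - expected_mz) / expected_mz * 1e6


def intensity_cv(intensities) -> float:
    """Coefficient of variation in percent: sample sd / mean × 100."""
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 intensities")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("intensities must be positive and finite")
    return float(np.std(x, ddof=1) / np.mean(x) * 100.0)


def calibration_fit(concentrations, intensities) -> tuple[float, float, float]:
    """OLS of intensity on concentration → (slope, intercept, r²)."""
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if np.unique(c).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    res = stats.linregress(c, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def match_standard_feature(features: pd.DataFrame, std: StandardDef):
    """Locate a standard in a feature-metadata table.

    LC platforms: nearest feature within 0.2 min RT and 10 ppm (smallest ppm
    wins).  GC (no accurate mass): nearest RT within 0.2 min.  Returns the
    feature id, or None when nothing matches.
    """
    drt = (features["rt_min"] - std.expected_rt).abs()
    cand = features[drt <= 0.2]
    if cand.empty:
        return None
    if std.expected_mz is None:
        return drt.loc[cand.index].idxmin()
    ppm = (cand["mz"] - std.expected_mz).abs() / std.expected_mz * 1e6
    cand = cand[ppm < 10.0]
    if cand.empty:
        return None
    return ppm.loc[cand.index].idxmin()


def qc_report(
    observations: pd.DataFrame,
    standards: list[StandardDef],
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Build the per-standard/per-batch QC report.

    ``observations`` has one row per standard detection in a QC_mix
    injection: columns standard, batch, observed_rt, observed_mz (NaN for
    GC), intensity, concentration.  Intra-batch CV pools replicate
    injections at the periodic (stability) concentration; extra-batch CV
    pools their batch means; calibration is fit per batch over the gradient
    and summarized as the mean r² per standard.  Metrics for a standard with
    no observations are recorded missing and flagged failed.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    by_std = dict(tuple(observations.groupby("standard")))
    per_batch_rows, per_std_rows = [], []
    flags: dict[str, dict[str, bool]] = {}

    for std in standards:
        obs = by_std.get(std.name)
        f: dict[str, bool] = {}
        if obs is None or obs.empty:
            per_std_rows.append(
                {"standard": std.name, "platform": std.platform,
                 "int_cv_extra": np.nan, "calibration_r2": np.nan,
                 "rt_dev_mean": np.nan, "mass_err_mean": np.nan}
            )
            flags[std.name] = {"detected": False}
            continue
        f["detected"] = True
        # replicate injections: the most frequent concentration is the
        # periodic stability level; gradient levels go to the calibration fit
        conc = obs["concentration"]
        if conc.notna().any():
            ref_conc = conc.value_counts().idxmax()
            reps = obs[conc == ref_conc]
        else:
            reps = obs
        batch_means = []
        rt_devs, mass_errs = [], []
        for b, grp in reps.groupby("batch"):
            rd = float(np.mean(rt_deviation(grp["observed_rt"], std.expected_rt)))
            me = np.nan
            if std.expected_mz is not None and grp["observed_mz"].notna().any():
                me = float(np.mean(mass_error_ppm(
                    grp["observed_mz"].dropna(), std.expected_mz)))
            cv = (intensity_cv(grp["intensity"]) if len(grp) >= 2 else np.nan)
            per_batch_rows.append(
                {"standard": std.name, "batch": b, "rt_dev_mean": rd,
                 "mass_err_mean": me, "int_cv_intra": cv}
            )
            batch_means.append(float(grp["intensity"].mean()))
            rt_devs.append(rd)
            if np.isfinite(me):
                mass_errs.append(me)
        cv_extra = intensity_cv(batch_means) if len(batch_means) >= 2 else np.nan
        r2s = []
        if conc.notna().any():
            grad = obs[conc.notna()]
            for b, grp in grad.groupby("batch"):
                if grp["concentration"].nunique() >= 3:
                    _, _, r2 = calibration_fit(grp["concentration"], grp["intensity"])
                    r2s.append(r2)
        r2_mean = float(np.mean(r2s)) if r2s else np.nan
        rt_mean = float(np.mean(rt_devs))
        me_mean = float(np.mean(mass_errs)) if mass_errs else np.nan
        per_std_rows.append(
            {"standard": std.name, "platform": std.platform,
             "int_cv_extra": cv_extra, "calibration_r2": r2_mean,
             "rt_dev_mean": rt_mean, "mass_err_mean": me_mean}
        )
        f["rt_dev"] = bool(abs(rt_mean) <= thresholds.rt_dev_abs_max)
        ppm_bound = thresholds.mass_err_ppm_max.get(std.platform)
        if ppm_bound is not None and np.isfinite(me_mean):
            f["mass_err"] = bool(abs(me_mean) < ppm_bound)
        if np.isfinite(cv_extra):
            f["int_cv_extra"] = bool(cv_extra < thresholds.int_cv_extra_max)
        if np.isfinite(r2_mean):
            f["calibration_r2"] = bool(r2_mean >= thresholds.calibration_r2_min)
        flags[std.name] = f

    return QCReport(
        per_batch=pd.DataFrame(per_batch_rows),
        per_standard=pd.DataFrame(per_std_rows),
        flags=flags,
    )
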