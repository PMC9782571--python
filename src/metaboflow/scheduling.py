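"""Injection-order randomization, batching, and QC interleaving.

Biological injections are randomized stratified by hospital, disease group,
gender, and age group (<55, 55-65, >=65 years) and split into fixed-size
acquisition batches (default 40).  Each batch is then fronted with a solvent
blank and a standards-mixture calibration gradient
(40, 27, 20, 13, 10, 7 µg/mL), and a (QC_mix, QC_bio, QC_NIST) triplet is
inserted after every ``qc_period`` biological injections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InjectionSchedule",
    "DEFAULT_GRADIENT",
    "age_group",
    "randomize_order",
    "interleave_qc",
]

#: Calibration-gradient concentrations in µg/mL, injected once per batch.
DEFAULT_GRADIENT = (40.0, 27.0, 20.0, 13.0, 10.0, 7.0)

#: Concentration (µg/mL) of the periodic stability QC_mix injections.
PERIODIC_QC_MIX_CONC = 20.0

SAMPLE_TYPES = ("bio", "QC_blank", "QC_mix", "QC_NIST", "QC_bio")


def age_group(age: float) -> str:
    """Age stratum: under 55, 55 to 65, 65 and older."""
    if age < 55:
        return "<55"
    if age < 65:
        return "55-65"
    return ">=65"


@dataclass
class InjectionSchedule:
    """Ordered injection list with batch assignment.

    ``entries`` columns: injection_index, sample_id, sample_type, batch,
    and (after interleaving) concentration for QC_mix injections.
    """

    entries: pd.DataFrame
    seed: int
    batch_size: int

    def __post_init__(self) -> None:
        idx = self.entries["injection_index"].to_numpy()
        if len(idx) and not (np.diff(idx) > 0).all():
            raise ValueError("injection_index must be strictly increasing")

    @property
    def n_batches(self) -> int:
        return int(self.entries["batch"].nunique())

    def biological(self) -> pd.DataFrame:
        return self.entries[self.entries["sample_type"] == "bio"]


def _strata_frame(samples: pd.DataFrame, strata_keys: list[str]) -> pd.Series:
    parts = []
    for key in strata_keys:
        if key == "age":
            col = samples["age"].map(age_group)
        else:
            col = samples[key].astype(str)
            bad = samples.loc[col.isin(["", "nan", "None"]) | samples[key].isna()]
            if len(bad):
                raise ValueError(
                    f"unknown value for stratum '{key}' in samples: "
                    f"{bad['sample_id'].tolist()[:10]}"
                )
        parts.append(col)
    return pd.Series(list(zip(*parts)), index=samples.index)


def randomize_order(
    samples: pd.DataFrame,
    strata_keys: list[str] | None = None,
    batch_size: int = 40,
    seed: int = 0,
    n_batches: int | None = None,
) -> InjectionSchedule:
    """Stratified randomization of biological samples into batches.

    ``samples`` needs columns sample_id, hospital, group, sex, age (or the
    configured ``strata_keys``).  Within each stratum, members are shuffled
    and dealt cyclically over batches through a global position counter, so
    every stratum's per-batch counts differ by at most one and batch totals
    stay within the configured size.  Batch contents are then shuffled.
    Deterministic given ``seed``.
    """
    if strata_keys is None:
        strata_keys = ["hospital", "group", "sex", "age"]
    samples = samples.reset_index(drop=True)
    n = len(samples)
    if n == 0:
        raise ValueError("no samples to schedule")
    min_batches = math.ceil(n / batch_size)
    if n_batches is None:
        n_batches = min_batches
    if n_batches < min_batches:
        raise ValueError(
            f"{n} samples cannot fit {n_batches} batches of {batch_size}"
        )
    rng = np.random.default_rng(seed)
    strata = _strata_frame(samples, strata_keys)

    batch_of = np.empty(n, dtype=int)
    counter = 0
    for _, idx in sorted(strata.groupby(strata).groups.items()):
        members = np.asarray(idx)
        rng.shuffle(members)
        for m in members:
            batch_of[m] = counter % n_batches
            counter += 1

    rows = []
    for b in range(n_batches):
        members = np.flatnonzero(batch_of == b)
        rng.shuffle(members)
        for m in members:
            rows.append((samples.at[m, "sample_id"], "bio", b))
    entries = pd.DataFrame(rows, columns=["sample_id", "sample_type", "batch"])
    entries.insert(0, "injection_index", np.arange(len(entries)))
    return InjectionSchedule(entries=entries, seed=seed, batch_size=batch_size)


def interleave_qc(
    schedule: InjectionSchedule,
    qc_period: int = 10,
    gradient: tuple[float, ...] = DEFAULT_GRADIENT,
) -> InjectionSchedule:
    """Insert QC injections into a biological schedule.

    Each batch starts with one QC_blank followed by the QC_mix calibration
    gradient; after every ``qc_period`` biological injections one
    (QC_mix, QC_bio, QC_NIST) triplet is inserted.  Biological order is
    never changed.
    """
    if qc_period < 1:
        raise ValueError("qc_period must be >= 1")
    if schedule.entries.empty:
        raise ValueError("schedule is empty")
    rows: list[tuple[str, str, int, float]] = []
    for b, grp in schedule.entries.groupby("batch", sort=True):
        rows.append((f"QCblank_b{b:03d}", "QC_blank", b, np.nan))
        for g, conc in enumerate(gradient):
            rows.append((f"QCmix_b{b:03d}_grad{g}", "QC_mix", b, conc))
        n_trip = 0
        for i, row in enumerate(grp.itertuples(index=False), start=1):
            rows.append((row.sample_id, "bio", b, np.nan))
            if i % qc_period == 0:
                n_trip += 1
                rows.append(
                    (f"QCmix_b{b:03d}_{n_trip}", "QC_mix", b, PERIODIC_QC_MIX_CONC)
                )
                rows.append((f"QCbio_b{b:03d}_{n_trip}", "QC_bio", b, np.nan))
                rows.append((f"QCnist_b{b:03d}_{n_trip}", "QC_NIST", b, np.nan))
    entries = pd.DataFrame(
        rows, columns=["sample_id", "sample_type", "batch", "concentration"]
    )
    entries.insert(0, "injection_index", np.arange(len(entries)))
    return InjectionSchedule(
        entries=entries, seed=schedule.seed, batch_size=schedule.batch_size
    )
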