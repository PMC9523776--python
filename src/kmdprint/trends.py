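"""Aging markers extracted from annotated fingerprint time courses.

Three marker families track time since deposition:

* **TG epoxide ratios** — each TG(E) species normalized to the saturated TG
  with the same carbon count (e.g. TG(E) 44:1 / TG 44:0), grouped by residual
  unsaturation.  Fully saturated epoxides (TG(E) X:0) plateau — epoxidation
  is monolayer-limited and the product is inert — while epoxides retaining
  C=C decay through further ozonolysis.
* **FA chain-length profiles** — disodiated fatty-acid intensities per chain
  length and age.  Long-chain FAs (13:0-18:0) are endogenous and flat;
  medium-chain FAs, above all FA 10:0 from ω-10 ozonide fragmentation,
  accumulate.
* **FA 10:0 marker** — FA 10:0 normalized to a contamination-free long-chain
  FA (default FA 15:0), monotonically non-decreasing with age.

All markers are intensity ratios within one sample and therefore invariant
to the amount of sebum deposited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedPeak
from .spectra import saturated_tg_signal

__all__ = [
    "TimeCourseSample",
    "TimeCourse",
    "MarkerSeries",
    "epoxide_ratio_series",
    "fa_profile_series",
    "fa10_marker",
    "tg_epoxide_vs_criegee",
]


@dataclass(frozen=True)
class TimeCourseSample:
    """One annotated sample of an aging series."""

    age_days: float
    replicate: int
    annotated: Sequence[AnnotatedPeak]


@dataclass(frozen=True)
class TimeCourse:
    samples: Sequence[TimeCourseSample]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("time course needs at least one sample")

    @property
    def ages(self) -> list[float]:
        return sorted({s.age_days for s in self.samples})


@dataclass(frozen=True)
class MarkerSeries:
    """Per-age mean ± sd of one marker (sd is NaN where n < 2)."""

    name: str
    ages: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age_days": self.ages, "mean": self.mean, "sd": self.sd, "n": self.n}
        )


def _aggregate(name: str, per_sample: list[tuple[float, float]]) -> MarkerSeries:
    by_age: dict[float, list[float]] = {}
    for age, value in per_sample:
        by_age.setdefault(age, []).append(value)
    ages = np.array(sorted(by_age))
    means = np.array([float(np.mean(by_age[a])) for a in ages])
    sds = np.array(
        [float(np.std(by_age[a], ddof=1)) if len(by_age[a]) >= 2 else np.nan
         for a in ages]
    )
    ns = np.array([len(by_age[a]) for a in ages])
    return MarkerSeries(name=name, ages=ages, mean=means, sd=sds, n=ns)


def _class_member_intensity(
    annotated: Iterable[AnnotatedPeak],
    n_O: int,
    n_Na: int,
    n_K: int,
    dbe: int,
    carbon: int,
) -> float:
    """Summed intensity assigned to one heteroatom-class member (0 if absent)."""
    total = 0.0
    for a in annotated:
        t = a.target
        if t is None:
            continue
        if (t.n_O, t.n_Na, t.n_K, t.dbe, t.carbon_number) == (
            n_O, n_Na, n_K, dbe, carbon,
        ):
            total += a.intensity
    return total


def epoxide_ratio_series(
    tc: TimeCourse,
    carbon_numbers: Sequence[int] = tuple(range(49, 55)),
    residual_db: int = 0,
) -> MarkerSeries:
    """TG epoxide / saturated-TG ratio series, grouped by residual C=C.

    For each acyl carbon count ``c`` the ratio is
    ``intensity(TG(E) c:residual_db) / intensity(TG c:0)``; per-sample values
    average over ``carbon_numbers`` and replicates aggregate as mean ± sd.
    Markers with a missing saturated-TG denominator are skipped with a
    warning.  The default carbon window sits in the high-mass TG range where
    the epoxide composition is not shadowed by an isomeric ozonolysis
    aldehyde of a heavier TG.
    """
    per_sample: list[tuple[float, float]] = []
    for sample in tc.samples:
        ratios: list[float] = []
        for acyl in carbon_numbers:
            c_formula = acyl + 3
            denom = _class_member_intensity(
                sample.annotated, 6, 1, 0, 3, c_formula
            )
            if denom <= 0.0:
                warnings.warn(
                    f"sample day {sample.age_days:g} rep {sample.replicate}: "
                    f"no saturated TG {acyl}:0 denominator; marker omitted"
                )
                continue
            numer = _class_member_intensity(
                sample.annotated, 7, 1, 0, 4 + residual_db, c_formula
            )
            ratios.append(numer / denom)
        if ratios:
            per_sample.append((sample.age_days, float(np.mean(ratios))))
    name = f"TG(E) X:{residual_db} / TG X:0"
    if not per_sample:
        return MarkerSeries(
            name, np.array([]), np.array([]), np.array([]), np.array([], dtype=int)
        )
    return _aggregate(name, per_sample)


def _fa_intensity(annotated, chain: int, db: int) -> float:
    # Disodiated FA class: C_c H_{2c-Z} O2 Na2, neutral-parent DBE = 1 + db.
    return _class_member_intensity(annotated, 2, 2, 0, 1 + db, chain)


def fa_profile_series(
    tc: TimeCourse,
    db: int = 0,
    chains: Sequence[int] = tuple(range(8, 21)),
    normalized: bool = True,
) -> pd.DataFrame:
    """Per-age FA intensity profile over chain lengths.

    Returns a long-form table (age_days, chain, mean, sd, n) of disodiated
    FA c:``db`` intensities; ``normalized`` divides each sample by its summed
    saturated-TG signal to cancel deposition differences.  Missing peaks
    count as zero intensity (below detection), keeping series aligned.
    """
    rows = []
    for chain in chains:
        per_sample = []
        for sample in tc.samples:
            value = _fa_intensity(sample.annotated, chain, db)
            if normalized:
                total = saturated_tg_signal(sample.annotated)
                value = value / total if total > 0 else np.nan
            per_sample.append((sample.age_days, value))
        series = _aggregate(f"FA {chain}:{db}", per_sample)
        for age, mean, sd, n in zip(series.ages, series.mean, series.sd, series.n):
            rows.append(
                {"age_days": age, "chain": chain, "mean": mean, "sd": sd, "n": n}
            )
    return pd.DataFrame(rows, columns=["age_days", "chain", "mean", "sd", "n"])


def tg_epoxide_vs_criegee(
    annotated: Iterable[AnnotatedPeak], epoxide_carbon_min: int = 52
) -> tuple[float, float]:
    """Summed TG epoxide signal vs summed disodiated TG Criegee-acid signal.

    TG(E) is measured in its O7/Na class restricted to formula carbon numbers
    >= ``epoxide_carbon_min`` — the high-mass window where no isomeric
    ozonolysis aldehyde of a heavier TG can share the composition — while
    TG(C) is the disodiated O8 class over all carbons.  Under sparse-ozone
    aging (singlet oxygen maintained, ozone ~5x lower) epoxidation outruns
    ozonolysis and TG(E) exceeds TG(C); under ambient aging it does not.
    """
    tge = tgc = 0.0
    for a in annotated:
        t = a.target
        if t is None or t.substrate_class != "TG" or t.n_K:
            continue
        if (
            t.n_O == 7
            and t.n_Na == 1
            and t.dbe >= 4
            and t.carbon_number >= epoxide_carbon_min
        ):
            tge += a.intensity
        elif t.n_O == 8 and t.n_Na == 2:
            tgc += a.intensity
    return tge, tgc


def fa10_marker(tc: TimeCourse, norm_chain: int = 15) -> MarkerSeries:
    """FA 10:0 normalized to an endogenous long-chain FA (default FA 15:0).

    FA 15:0 (or 17:0) is preferred as the normalizer because it is endogenous,
    stable with age and least prone to contamination.  Raises if the
    normalizer is absent from any sample.
    """
    per_sample: list[tuple[float, float]] = []
    for sample in tc.samples:
        norm = _fa_intensity(sample.annotated, norm_chain, 0)
        if norm <= 0.0:
            raise ValueError(
                f"normalizing FA {norm_chain}:0 missing in sample "
                f"day {sample.age_days:g} rep {sample.replicate}"
            )
        per_sample.append((sample.age_days, _fa_intensity(sample.annotated, 10, 0) / norm))
    return _aggregate(f"FA 10:0 / FA {norm_chain}:0", per_sample)
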