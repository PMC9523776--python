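"""Peak annotation against the theoretical target list at ±2 ppm.

Each centroid is assigned to the minimum-|ppm| target within tolerance
(binary search over the m/z-sorted list).  Ties at equal |ppm| prefer Na over
K adducts, substrates over products, and lower oxygen count — potassium
adducts are minor and must not outcompete the sodium interpretation.

Two diagnostic flags are attached:

* ``type2_isotope_risk`` — the near-isobaric clash where the second-¹³C
  isotopologue of a lipid with one more double bond sits only 0.0089 Da
  (2·(¹³C−¹²C) vs H2) below the assigned monoisotopic peak;
* ``multi_class_ambiguous`` — the assigned composition is shared by several
  classes (isomers, e.g. the TG(A)/TG(E) O7 family) or another class lies
  within tolerance.

Class intensity profiles (intensity vs carbon number along one heteroatom
class) are the basis for separating the ozonolysis-aldehyde population from
the epoxide population, which share a class but occupy different mass
regions; :func:`split_bimodal_profile` finds the valley between the two modes
of a smoothed profile.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import C13_C12_DELTA
from .oxidation import TargetEntry, _TAG_RANK

__all__ = [
    "AnnotatedPeak",
    "ClassProfile",
    "annotate_peaks",
    "annotation_frame",
    "flag_type2_interference",
    "class_intensity_profile",
    "split_bimodal_profile",
]

#: Isotopic abundance of 13C used for expected-isotopologue estimates.
C13_ABUNDANCE = 0.0107

#: Type-II gap: second 13C isotopologue vs one-more-saturation monoisotopic.
TYPE2_GAP_DA = abs(2 * C13_C12_DELTA - 2 * 1.00782503207)


@dataclass(frozen=True)
class AnnotatedPeak:
    """A centroid joined to its best target (or None if unassigned)."""

    mz: float
    intensity: float
    target: TargetEntry | None = None
    ppm_error: float | None = None
    alternates: tuple[TargetEntry, ...] = ()
    flags: frozenset[str] = frozenset()

    @property
    def assigned(self) -> bool:
        return self.target is not None

    def with_flag(self, flag: str) -> "AnnotatedPeak":
        return replace(self, flags=self.flags | {flag})


def _tie_break_key(mz: float, target: TargetEntry):
    ppm = (mz - target.mz) / target.mz * 1e6
    return (round(abs(ppm), 6), target.n_K, _TAG_RANK[target.product_tag], target.n_O)


def annotate_peaks(
    peaks, targets: Sequence[TargetEntry], tol_ppm: float = 2.0
) -> list[AnnotatedPeak]:
    """Assign each peak to the closest target within ``tol_ppm``.

    ``peaks`` is a :class:`~kmdprint.spectra.PeakList` (or anything exposing
    ``mz``/``intensity`` arrays).  Unassigned peaks are kept with
    ``target=None``.  The result is deterministic and independent of peak
    order.
    """
    targets = sorted(targets, key=lambda t: t.mz)
    target_mzs = [t.mz for t in targets]
    annotated: list[AnnotatedPeak] = []
    for mz, intensity in zip(
        np.asarray(peaks.mz, dtype=float), np.asarray(peaks.intensity, dtype=float)
    ):
        tol = tol_ppm * 1e-6 * mz
        lo = bisect_left(target_mzs, mz - tol)
        hi = bisect_right(target_mzs, mz + tol)
        candidates = targets[lo:hi]
        if not candidates:
            annotated.append(AnnotatedPeak(mz=float(mz), intensity=float(intensity)))
            continue
        candidates.sort(key=lambda t: _tie_break_key(mz, t))
        best = candidates[0]
        ppm = (mz - best.mz) / best.mz * 1e6
        flags = set()
        if best.n_K > 0:
            flags.add("potassium_adduct")
        alternates = tuple(candidates[1:])
        if len(best.labels) > 1 or any(
            a.class_key != best.class_key for a in alternates
        ):
            flags.add("multi_class_ambiguous")
        annotated.append(
            AnnotatedPeak(
                mz=float(mz),
                intensity=float(intensity),
                target=best,
                ppm_error=float(ppm),
                alternates=alternates,
                flags=frozenset(flags),
            )
        )
    return annotated


def _second_isotopologue_fraction(n_carbon: int, r: float = C13_ABUNDANCE) -> float:
    """Binomial M+2/M intensity ratio for a carbon count ``n_carbon``."""
    if n_carbon < 2:
        return 0.0
    return math.comb(n_carbon, 2) * (r / (1.0 - r)) ** 2


def flag_type2_interference(
    annotated: Sequence[AnnotatedPeak],
    expected_fraction: float = 0.2,
    search_window_da: float = 0.012,
) -> list[AnnotatedPeak]:
    """Flag assigned peaks at risk of Type-II isotopic overlap.

    For an assigned peak at m/z ``m``, look for a peak near ``m - 2*(13C-12C)``
    (the window covers the 0.0089 Da Type-II gap).  If that peak's expected
    second-isotopologue contribution — its intensity times the binomial M+2/M
    ratio for its carbon count — is at least ``expected_fraction`` of the
    assigned peak, the assignment is flagged ``type2_isotope_risk``.
    """
    mzs = [a.mz for a in annotated]
    out: list[AnnotatedPeak] = []
    for peak in annotated:
        if not peak.assigned:
            out.append(peak)
            continue
        center = peak.mz - 2 * C13_C12_DELTA
        lo = bisect_left(mzs, center - search_window_da)
        hi = bisect_right(mzs, center + search_window_da)
        flagged = False
        for other in annotated[lo:hi]:
            if other is peak:
                continue
            if other.assigned:
                n_c = other.target.composition.total_carbon
            else:
                # Lipid-like estimate: roughly one carbon per 15 Da.
                n_c = max(2, round(other.mz / 15.0))
            expected = other.intensity * _second_isotopologue_fraction(n_c)
            if expected >= expected_fraction * peak.intensity:
                flagged = True
                break
        out.append(peak.with_flag("type2_isotope_risk") if flagged else peak)
    return out


def annotation_frame(annotated: Sequence[AnnotatedPeak]) -> pd.DataFrame:
    """Flat annotation table (TSV-ready)."""
    rows = []
    for a in annotated:
        rows.append(
            {
                "mz": a.mz,
                "intensity": a.intensity,
                "label": a.target.label if a.assigned else "",
                "formula": a.target.composition.formula() if a.assigned else "",
                "mz_theoretical": a.target.mz if a.assigned else np.nan,
                "ppm_error": a.ppm_error if a.assigned else np.nan,
                "c": a.target.carbon_number if a.assigned else pd.NA,
                "DBE": a.target.dbe if a.assigned else pd.NA,
                "flags": ";".join(sorted(a.flags)),
                "alternates": ";".join(t.label for t in a.alternates),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mz", "intensity", "label", "formula", "mz_theoretical",
            "ppm_error", "c", "DBE", "flags", "alternates",
        ],
    )


@dataclass(frozen=True)
class ClassProfile:
    """Intensity vs carbon number along one heteroatom class (fixed DBE)."""

    n_O: int
    dbe: int
    n_Na: int
    n_K: int
    carbon_numbers: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str | None = None

    def __len__(self) -> int:
        return int(self.carbon_numbers.size)


def class_intensity_profile(
    annotated: Iterable[AnnotatedPeak],
    n_O: int,
    dbe: int,
    n_Na: int = 1,
    n_K: int = 0,
    sample_id: str | None = None,
) -> ClassProfile:
    """Sum assigned intensities per carbon number for one class.

    The class is keyed by oxygen count, adduct content and neutral-parent DBE
    (e.g. ``n_O=7, dbe=4`` is the shared TG(A)/TG(E) family).  A valid class
    with no assigned peaks yields an empty profile.
    """
    if n_O < 0 or dbe < 1 or n_Na < 0 or n_K < 0:
        raise ValueError("invalid heteroatom class parameters")
    sums: dict[int, float] = {}
    mz_rep: dict[int, float] = {}
    for a in annotated:
        t = a.target
        if t is None:
            continue
        if (t.n_O, t.n_Na, t.n_K, t.dbe) != (n_O, n_Na, n_K, dbe):
            continue
        c = t.carbon_number
        sums[c] = sums.get(c, 0.0) + a.intensity
        mz_rep.setdefault(c, t.mz)
    carbons = np.array(sorted(sums), dtype=int)
    return ClassProfile(
        n_O=n_O,
        dbe=dbe,
        n_Na=n_Na,
        n_K=n_K,
        carbon_numbers=carbons,
        mz=np.array([mz_rep[c] for c in carbons]),
        intensity=np.array([sums[c] for c in carbons]),
        sample_id=sample_id,
    )


@dataclass(frozen=True)
class ProfileSplit:
    """Result of a bimodal split: 1-2 modes plus the valley carbon number."""

    modes: tuple[ClassProfile, ...]
    valley_carbon: int | None

    @property
    def is_bimodal(self) -> bool:
        return len(self.modes) == 2


def _subprofile(profile: ClassProfile, mask: np.ndarray) -> ClassProfile:
    return replace(
        profile,
        carbon_numbers=profile.carbon_numbers[mask],
        mz=profile.mz[mask],
        intensity=profile.intensity[mask],
    )


def split_bimodal_profile(
    profile: ClassProfile, min_members: int = 5
) -> ProfileSplit:
    """Split a class profile at the valley between its two largest modes.

    The profile is laid out on a dense carbon grid (absent members at zero),
    smoothed with a 3-point moving average, and its local maxima located.
    With >= 2 maxima the split point is the minimum of the smoothed profile
    between the two largest; otherwise the profile is returned as one mode.
    The low-mass mode of the shared O7 TG family is the ozonolysis-aldehyde
    population TG(A), the high-mass mode the epoxide population TG(E).
    """
    n = len(profile)
    if n == 0:
        return ProfileSplit(modes=(), valley_carbon=None)
    if n < min_members:
        return ProfileSplit(modes=(profile,), valley_carbon=None)
    c_lo, c_hi = int(profile.carbon_numbers[0]), int(profile.carbon_numbers[-1])
    grid = np.arange(c_lo, c_hi + 1)
    dense = np.zeros(grid.size)
    dense[profile.carbon_numbers - c_lo] = profile.intensity
    smooth = np.convolve(dense, np.ones(3) / 3.0, mode="same")
    maxima = [
        i
        for i in range(grid.size)
        if smooth[i] > 0
        and (i == 0 or smooth[i] >= smooth[i - 1])
        and (i == grid.size - 1 or smooth[i] >= smooth[i + 1])
    ]
    if len(maxima) < 2:
        return ProfileSplit(modes=(profile,), valley_carbon=None)
    top_two = sorted(sorted(maxima, key=lambda i: smooth[i])[-2:])
    left, right = top_two
    if right - left < 2:
        return ProfileSplit(modes=(profile,), valley_carbon=None)
    interior = np.arange(left + 1, right)
    valley_idx = interior[np.argmin(smooth[interior])]
    valley_c = int(grid[valley_idx])
    low = profile.carbon_numbers <= valley_c
    return ProfileSplit(
        modes=(_subprofile(profile, low), _subprofile(profile, ~low)),
        valley_carbon=valley_c,
    )
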