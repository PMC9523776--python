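"""Kendrick mass / Kendrick mass defect computation and homolog grouping.

The Kendrick mass rescales m/z by 14/14.01565 (14.01565... Da being the exact
mass of the CH2 alkyl-chain unit) so that homologs differing only in CH2
count land exactly 14 apart.  The Kendrick mass defect,

    KMD = round(KM) - KM,

is then identical within a homologous series: the series aligns horizontally
in a KMD-vs-m/z plot, and parallel series one degree of unsaturation apart
are offset by |ΔKMD| = 0.0134 (0.013399... in closed form — the Kendrick-
rescaled H2 mass minus 2).

Sign and rounding conventions: ``round(KM) - KM`` with round-half-up, which
places the sebum-lipid window at positive KMD 0.05-0.35.  Note that part of
the wider literature instead uses ``KM - floor(KM)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chem import ElementalComposition, monoisotopic_mass

__all__ = [
    "CH2_MASS",
    "KENDRICK_SCALE",
    "DELTA_KMD_PER_UNSATURATION",
    "KendrickPoint",
    "kendrick_mass",
    "kendrick_mass_defect",
    "group_homologous_series",
    "kmd_plot_data",
]

#: Exact monoisotopic mass of the CH2 repeat unit (Da).
CH2_MASS = monoisotopic_mass(ElementalComposition(n_C=1, n_H=2))

#: m/z -> Kendrick mass factor, 14 / 14.01565...
KENDRICK_SCALE = 14.0 / CH2_MASS

_H2_KENDRICK = monoisotopic_mass(ElementalComposition(n_H=2)) * KENDRICK_SCALE

#: |KMD| offset between homologous series one degree of unsaturation apart.
DELTA_KMD_PER_UNSATURATION = _H2_KENDRICK - 2.0  # 0.013399...


def _check_positive(mz) -> np.ndarray:
    arr = np.asarray(mz, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("m/z values must be positive")
    return arr


def kendrick_mass(mz):
    """Kendrick mass ``mz * 14/14.01565``; accepts scalars or arrays."""
    arr = _check_positive(mz)
    km = arr * KENDRICK_SCALE
    return float(km) if np.isscalar(mz) else km


def kendrick_mass_defect(mz):
    """KMD = round-half-up(KM) - KM; always in [-0.5, 0.5]."""
    arr = _check_positive(mz)
    km = arr * KENDRICK_SCALE
    kmd = np.floor(km + 0.5) - km
    return float(kmd) if np.isscalar(mz) else kmd


@dataclass(frozen=True)
class KendrickPoint:
    """One centroid in Kendrick coordinates."""

    mz: float
    intensity: float = 0.0
    sample_id: str | None = None
    label: str | None = None

    @property
    def km(self) -> float:
        return kendrick_mass(self.mz)

    @property
    def kmd(self) -> float:
        return kendrick_mass_defect(self.mz)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _is_ch2_spacing(m1: float, m2: float, ppm_tol: float) -> bool:
    gap = abs(m2 - m1)
    k = round(gap / CH2_MASS)
    return abs(gap - k * CH2_MASS) <= ppm_tol * 1e-6 * max(m1, m2)


def group_homologous_series(
    points: Sequence[KendrickPoint],
    kmd_tol: float = 0.0005,
    ppm_tol: float = 2.0,
) -> list[list[KendrickPoint]]:
    """Group points into homologous series.

    Two points join a series when their KMD differ by <= ``kmd_tol`` and
    their m/z gap is an integer multiple of the CH2 mass within ``ppm_tol``;
    series membership is the transitive closure of that relation.  Each
    returned series is sorted by m/z (i.e. by carbon number).
    """
    pts = list(points)
    if not pts:
        return []
    kmds = np.array([p.kmd for p in pts])
    order = np.argsort(kmds, kind="stable")
    uf = _UnionFind(len(pts))
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1:]:
            if kmds[j] - kmds[i] > kmd_tol:
                break
            if _is_ch2_spacing(pts[i].mz, pts[j].mz, ppm_tol):
                uf.union(i, j)
    groups: dict[int, list[KendrickPoint]] = {}
    for i, p in enumerate(pts):
        groups.setdefault(uf.find(i), []).append(p)
    series = [sorted(g, key=lambda p: p.mz) for g in groups.values()]
    series.sort(key=lambda g: g[0].mz)
    return series


def kmd_plot_data(
    peaks,
    kmd_range: tuple[float, float] = (0.05, 0.35),
    mz_range: tuple[float, float] = (100.0, 1200.0),
    sn_threshold: float = 30.0,
    noise_level: float | None = None,
) -> pd.DataFrame:
    """Overlay-ready KMD plot table from a peak list.

    Filters to the lipid KMD window (default 0.05-0.35), the instrument m/z
    range and an S/N threshold (default 30).  ``peaks`` is a
    :class:`~kmdprint.spectra.PeakList` or any object with ``mz``/``intensity``
    arrays; S/N uses the peak list's ``noise_level`` metadata when present,
    else the median intensity.
    """
    if kmd_range[0] >= kmd_range[1] or mz_range[0] >= mz_range[1]:
        raise ValueError("inverted kmd/mz range")
    mz = np.asarray(peaks.mz, dtype=float)
    intensity = np.asarray(peaks.intensity, dtype=float)
    sample_id = getattr(peaks, "sample_id", None)
    if noise_level is None:
        noise_level = getattr(peaks, "noise_level", None)
    if mz.size == 0:
        return pd.DataFrame(
            columns=["mz", "km", "kmd", "intensity", "sn", "sample_id"]
        )
    if noise_level is None or noise_level <= 0:
        med = np.median(intensity)
        noise_level = med if med > 0 else 1.0
    sn = intensity / noise_level
    km = mz * KENDRICK_SCALE
    kmd = np.floor(km + 0.5) - km
    keep = (
        (kmd >= kmd_range[0])
        & (kmd <= kmd_range[1])
        & (mz >= mz_range[0])
        & (mz <= mz_range[1])
        & (sn > sn_threshold)
    )
    return pd.DataFrame(
        {
            "mz": mz[keep],
            "km": km[keep],
            "kmd": kmd[keep],
            "intensity": intensity[keep],
            "sn": sn[keep],
            "sample_id": sample_id,
        }
    )
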