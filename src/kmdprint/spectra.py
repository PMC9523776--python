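"""Centroid peak-list container, TSV I/O, normalization and subtraction.

The native exchange format is a plain tab-separated centroid table with
``mz``/``intensity`` columns and ``#``-prefixed metadata header lines
(``sample_id``, ``age_days``, ``replicate``, ``noise_level``, ``normalized``).
Values round-trip bit-exactly at six decimals.

To compare fingerprints deposited with different amounts of sebum, spectra
are normalized to the summed signal of saturated (DBE 3) triacylglycerols
before subtraction; the subtracted spectrum (aged minus fresh) then exposes
gains (oxidation products) and losses (consumed unsaturated lipids, squalene)
directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "SubtractedSpectrum",
    "read_peaklist",
    "write_peaklist",
    "normalize_to_saturated_tg",
    "saturated_tg_signal",
    "subtract_spectra",
]


@dataclass(frozen=True)
class PeakList:
    """One sample's centroids plus acquisition metadata.

    ``mz`` must be strictly increasing and intensities non-negative.
    ``noise_level`` (same unit as intensity) supports S/N filtering;
    ``normalized`` records whether intensities are on the saturated-TG scale.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = "sample"
    age_days: float = 0.0
    replicate: int = 1
    noise_level: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and (np.any(mz <= 0) or np.any(mz >= 10000)):
            raise ValueError("m/z values must lie in (0, 10000)")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(intensity < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "age_days", float(self.age_days))
        object.__setattr__(self, "replicate", int(self.replicate))
        if self.age_days < 0:
            raise ValueError("age_days must be >= 0")

    def __len__(self) -> int:
        return int(self.mz.size)

    def sn(self) -> np.ndarray:
        """Signal-to-noise per peak: intensity / noise_level (or / median)."""
        if self.noise_level and self.noise_level > 0:
            return self.intensity / self.noise_level
        med = np.median(self.intensity) if len(self) else 1.0
        return self.intensity / (med if med > 0 else 1.0)

    def scaled(self, factor: float, normalized: bool | None = None) -> "PeakList":
        return replace(
            self,
            intensity=self.intensity * factor,
            normalized=self.normalized if normalized is None else normalized,
        )


_META_FIELDS = ("sample_id", "age_days", "replicate", "noise_level", "normalized")


def write_peaklist(peaks: PeakList, path) -> None:
    path = Path(path)
    lines = []
    for name in _META_FIELDS:
        value = getattr(peaks, name)
        if value is None:
            continue
        lines.append(f"# {name}: {value}\n")
    lines.append("mz\tintensity\n")
    for mz, inten in zip(peaks.mz, peaks.intensity):
        lines.append(f"{mz:.6f}\t{inten:.6f}\n")
    path.write_text("".join(lines))


def _merge_duplicates(mz: np.ndarray, intensity: np.ndarray):
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    unique, inverse = np.unique(mz, return_inverse=True)
    if unique.size == mz.size:
        return mz, intensity, False
    summed = np.zeros_like(unique)
    np.add.at(summed, inverse, intensity)
    return unique, summed, True


def read_peaklist(path) -> PeakList:
    """Read the centroid TSV dialect written by :func:`write_peaklist`.

    Rows are sorted ascending on read; duplicate m/z rows are merged by
    summing intensity (with a warning).  A malformed data row raises with its
    line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    mzs: list[float] = []
    intens: list[float] = []
    header_seen = False
    with path.open() as handle:
        for lineno, rawline in enumerate(handle, start=1):
            line = rawline.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, value = line.lstrip("# ").partition(":")
                    meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = [c.strip().lower() for c in line.split("\t")]
                if cols[:2] != ["mz", "intensity"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'mz<TAB>intensity'"
                    )
                header_seen = True
                continue
            parts = line.split("\t")
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
    if not header_seen:
        raise ValueError(f"{path}: missing 'mz\\tintensity' header")
    mz, intensity, merged = _merge_duplicates(
        np.asarray(mzs, dtype=float), np.asarray(intens, dtype=float)
    )
    if merged:
        warnings.warn(f"{path}: duplicate m/z rows merged by intensity sum")
    noise = meta.get("noise_level")
    return PeakList(
        mz=mz,
        intensity=intensity,
        sample_id=meta.get("sample_id", path.stem),
        age_days=float(meta.get("age_days", 0.0)),
        replicate=int(meta.get("replicate", 1)),
        noise_level=float(noise) if noise not in (None, "None") else None,
        normalized=meta.get("normalized", "False") == "True",
    )


def _is_saturated_tg(target) -> bool:
    return (
        target is not None
        and target.substrate_class == "TG"
        and target.product_tag == "substrate"
        and target.dbe == 3
    )


def saturated_tg_signal(annotated) -> float:
    """Summed intensity of peaks annotated as saturated-TG substrates."""
    return float(
        sum(a.intensity for a in annotated if _is_saturated_tg(a.target))
    )


def normalize_to_saturated_tg(peaks: PeakList, annotated) -> PeakList:
    """Divide every intensity by the summed saturated-TG substrate signal.

    ``annotated`` is the annotation of this peak list (see
    :func:`kmdprint.annotate.annotate_peaks`).  After normalization the
    saturated-TG sum equals 1, cancelling deposition differences between
    samples; normalizing an already-normalized list is a no-op re-scaling by
    its (unit) saturated-TG sum, so the operation is idempotent.
    """
    total = saturated_tg_signal(annotated)
    if total <= 0:
        raise ValueError(
            "no saturated-TG substrate signal found; normalization undefined"
        )
    if peaks.noise_level is not None:
        scaled = replace(
            peaks,
            intensity=peaks.intensity / total,
            noise_level=peaks.noise_level / total,
            normalized=True,
        )
    else:
        scaled = peaks.scaled(1.0 / total, normalized=True)
    return scaled


@dataclass(frozen=True)
class SubtractedSpectrum:
    """Aligned bins of aged-minus-fresh intensity differences."""

    mz: np.ndarray
    delta: np.ndarray
    match_tol_ppm: float
    fresh_id: str = "fresh"
    aged_id: str = "aged"

    def delta_at(self, mz: float, tol_ppm: float | None = None) -> float:
        """Summed Δintensity within ``tol_ppm`` of ``mz`` (0 if none)."""
        tol = (tol_ppm if tol_ppm is not None else self.match_tol_ppm) * 1e-6 * mz
        mask = np.abs(self.mz - mz) <= tol
        return float(self.delta[mask].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mz": self.mz, "delta_intensity": self.delta})


def subtract_spectra(
    fresh: PeakList, aged: PeakList, match_tol_ppm: float = 2.0
) -> SubtractedSpectrum:
    """Aged minus fresh after matching peaks within ``match_tol_ppm``.

    Both inputs must be deposition-normalized.  Peaks are paired greedily by
    smallest ppm distance (each peak used at most once); unmatched peaks are
    kept with the absent side counted as zero.  Matched bins are reported at
    the midpoint m/z so that ``subtract(a, b) == -subtract(b, a)`` bin-wise.
    """
    if not (fresh.normalized and aged.normalized):
        raise ValueError("subtract_spectra requires normalized peak lists")
    candidates: list[tuple[float, int, int]] = []
    for i, mz in enumerate(fresh.mz):
        tol = match_tol_ppm * 1e-6 * mz
        lo = np.searchsorted(aged.mz, mz - tol, side="left")
        hi = np.searchsorted(aged.mz, mz + tol, side="right")
        for j in range(lo, hi):
            candidates.append((abs(aged.mz[j] - mz) / mz, i, j))
    candidates.sort()
    used_fresh: set[int] = set()
    used_aged: set[int] = set()
    rows: list[tuple[float, float]] = []
    for _, i, j in candidates:
        if i in used_fresh or j in used_aged:
            continue
        used_fresh.add(i)
        used_aged.add(j)
        rows.append(
            (0.5 * (fresh.mz[i] + aged.mz[j]), aged.intensity[j] - fresh.intensity[i])
        )
    for i, mz in enumerate(fresh.mz):
        if i not in used_fresh:
            rows.append((float(mz), -float(fresh.intensity[i])))
    for j, mz in enumerate(aged.mz):
        if j not in used_aged:
            rows.append((float(mz), float(aged.intensity[j])))
    rows.sort()
    mz_arr = np.array([r[0] for r in rows])
    delta = np.array([r[1] for r in rows])
    return SubtractedSpectrum(
        mz=mz_arr,
        delta=delta,
        match_tol_ppm=match_tol_ppm,
        fresh_id=fresh.sample_id,
        aged_id=aged.sample_id,
    )
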