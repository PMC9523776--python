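"""Ground-truthed synthetic fingerprint MALDI spectra.

A forward model of sebaceous-fingerprint aging and its MALDI measurement, so
that every analysis stage can be exercised against known truth:

* a TG-dominated sebum composition with SQ, WE, DG and endogenous FA
  (including sapienic acid FA 16:1), ω-10-biased double-bond positions;
* first-order ambient ozonolysis per C=C (rate ``k_ozonolysis``/day) feeding
  a persistent secondary-ozonide pool that fragments in-source during MALDI
  into the head aldehyde (A), the Criegee isomers (B/C, partly detected as
  the disodiated acid C) and the released tail acid (the FA ω:0 that makes
  FA 10:0 an aging marker);
* rapid, monolayer-capped epoxidation (product E) at deposition time —
  epoxides of monounsaturated lipids are then inert, epoxides with residual
  C=C keep ozonolyzing away;
* sequential (double) ozonolysis for multi-unsaturated DG/WE/TG;
* measurement effects: sodiated (acids: disodiated) ions with Gaussian ppm
  jitter, binomial ¹³C isotopologues (M+1, M+2), minor potassium-adduct
  twins, multiplicative intensity noise, additive noise peaks, and a
  per-replicate deposition factor.

Squalene decays fastest (six C=C) and its products are volatile: they leave
the spectrum rather than forming ozonide ions.

All kinetics are solved in closed form, so species mass balance holds to
numerical precision and identical seeds give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ElementalComposition, ion_mz
from .oxidation import (
    SQUALENE,
    LipidSpecies,
    compose_lipid,
    species_name,
)
from .spectra import PeakList

__all__ = [
    "SebumProfile",
    "AgingParams",
    "SpeciesPools",
    "SimulatedSample",
    "default_sebum_profile",
    "ambient_params",
    "sparse_ozone_params",
    "age_profile",
    "render_spectrum",
    "generate_timecourse",
]

_O = ElementalComposition(n_O=1)
_NA = ElementalComposition(n_Na=1)
_H = ElementalComposition(n_H=1)


@dataclass(frozen=True)
class SebumProfile:
    """Relative species abundances plus the ω-position prior.

    ``omega_weights`` is the probability that an unsaturated acyl chain's
    reacting C=C sits at ω-n; the default puts 0.65 on ω-10 with ω-8/9/11
    sharing the rest, reflecting the dominance of ω-10 acyl chains in sebum.
    """

    species: Mapping[LipidSpecies, float]
    omega_weights: Mapping[int, float] = field(
        default_factory=lambda: {8: 0.10, 9: 0.15, 10: 0.65, 11: 0.10}
    )
    deposition_factor: float = 1.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.species.values()):
            raise ValueError("species abundances must be >= 0")
        total = sum(self.omega_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("omega weights must sum to 1")


@dataclass(frozen=True)
class AgingParams:
    """Simulator kinetics and measurement noise.

    Rates and branching fractions are free parameters of the forward model
    (config-exposed, not literature constants); defaults encode the ambient
    laboratory scenario.
    """

    k_ozonolysis: float = 0.5          # per C=C per day
    epoxide_cap: float = 0.05          # monolayer fraction epoxidized at t=0+
    branch_intact_ozonide: float = 0.60
    branch_insource_a: float = 0.25
    branch_insource_bc: float = 0.15
    frac_criegee_disodiated: float = 0.5
    c13_abundance: float = 0.0107
    mz_jitter_ppm: float = 0.5
    intensity_cv: float = 0.08
    k_adduct_fraction: float = 0.04
    deposition_cv: float = 0.2
    n_noise_peaks: int = 150
    noise_floor: float = 100.0
    base_scale: float = 1.0e6
    min_intensity: float = 10.0
    mz_range: tuple[float, float] = (100.0, 1200.0)
    merge_tol_da: float = 0.001

    def __post_init__(self) -> None:
        branches = (
            self.branch_intact_ozonide
            + self.branch_insource_a
            + self.branch_insource_bc
        )
        if not math.isclose(branches, 1.0, abs_tol=1e-9):
            raise ValueError("ozonide branching probabilities must sum to 1")
        if self.k_ozonolysis < 0 or not 0 <= self.epoxide_cap <= 1:
            raise ValueError("invalid kinetics parameters")
        if self.mz_jitter_ppm > 2.0:
            raise ValueError("mz jitter sd must be <= 2 ppm")


def ambient_params(**overrides) -> AgingParams:
    """Ambient-laboratory aging scenario (the default parameter set)."""
    return replace(AgingParams(), **overrides) if overrides else AgingParams()


def sparse_ozone_params(**overrides) -> AgingParams:
    """Sparse-ozone climate-chamber scenario: ~5x less ozone, but singlet
    oxygen maintained — ozonolysis slowed 5x, epoxide monolayer cap doubled."""
    base = AgingParams()
    params = replace(
        base,
        k_ozonolysis=base.k_ozonolysis / 5.0,
        epoxide_cap=min(1.0, base.epoxide_cap * 2.0),
    )
    return replace(params, **overrides) if overrides else params


def default_sebum_profile(seed: int = 0) -> SebumProfile:
    """TG-dominant sebum mixture; reproducible for a given seed.

    TGs span acyl C40-C56 with 0-3 C=C centred near TG 48; SQ is abundant in
    fresh sebum; WE/DG minor; endogenous FAs cover 13:0-18:1 (sapienic acid
    16:1 included).  FA 10:0 starts at zero — medium-chain FAs are rare in
    nature and appear only as ozonolysis fragments.
    """
    rng = np.random.default_rng(seed)
    species: dict[LipidSpecies, float] = {}

    def jitter() -> float:
        return float(np.clip(1.0 + 0.05 * rng.standard_normal(), 0.5, 1.5))

    db_weight = {0: 1.0, 1: 0.75, 2: 0.45, 3: 0.20}
    for acyl in range(40, 57):
        # Narrow envelope: the abundant TGs sit in a ~10-carbon window
        # (sodiated ions m/z ~770-900).
        shape = math.exp(-0.5 * ((acyl - 48) / 2.5) ** 2)
        for d in range(0, 4):
            species[LipidSpecies("TG", acyl, d)] = shape * db_weight[d] * jitter()

    species[SQUALENE] = 5.0 * jitter()

    for chain in range(30, 41, 2):
        shape = 0.5 * math.exp(-0.5 * ((chain - 34) / 4.0) ** 2)
        for d in (0, 1):
            species[LipidSpecies("WE", chain, d)] = shape * (1.0, 0.5)[d] * jitter()

    for acyl in range(30, 37, 2):
        shape = 0.3 * math.exp(-0.5 * ((acyl - 32) / 3.0) ** 2)
        for d in (0, 1):
            species[LipidSpecies("DG", acyl, d)] = shape * (1.0, 0.5)[d] * jitter()

    endogenous_fa = {
        (13, 0): 0.20, (14, 0): 0.50, (15, 0): 0.40, (16, 0): 1.20,
        (16, 1): 0.80, (17, 0): 0.20, (18, 0): 0.50, (18, 1): 0.60,
    }
    for (chain, d), ab in endogenous_fa.items():
        species[LipidSpecies("FA", chain, d)] = ab * jitter()

    total = sum(species.values())
    return SebumProfile(
        species={sp: ab / total for sp, ab in species.items()}
    )


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesPools:
    """Where one substrate's initial abundance resides after ``t`` days."""

    species: LipidSpecies
    initial: float
    substrate: float
    epoxide: float
    epoxide_lost: float
    ozonide: Mapping[int, float]          # first-cleavage pool, by omega
    ozonide2: Mapping[tuple[int, int], float]  # second cleavage, by omega pair
    volatile_lost: float

    def total(self) -> float:
        return (
            self.substrate
            + self.epoxide
            + self.epoxide_lost
            + sum(self.ozonide.values())
            + sum(self.ozonide2.values())
            + self.volatile_lost
        )


def _omega_weights(
    species: LipidSpecies, profile: SebumProfile
) -> dict[int, float]:
    if species.db_positions:
        weights: dict[int, float] = {}
        for w in species.db_positions:
            weights[w] = weights.get(w, 0.0) + 1.0 / species.n_db
        return weights
    return dict(profile.omega_weights)


def _species_pools(
    species: LipidSpecies,
    abundance: float,
    days: float,
    params: AgingParams,
    profile: SebumProfile,
) -> SpeciesPools:
    d = species.n_db
    k = params.k_ozonolysis
    if d == 0 or abundance == 0.0:
        return SpeciesPools(
            species, abundance, abundance, 0.0, 0.0, {}, {}, 0.0
        )
    eps = params.epoxide_cap
    s0 = abundance * (1.0 - eps)
    e0 = abundance * eps
    a = d * k
    substrate = s0 * math.exp(-a * days)
    double_allowed = species.lipid_class in ("DG", "WE", "TG") and d >= 2
    b = (d - 1) * k if double_allowed else 0.0
    if k == 0.0:
        oz1_total = oz2_total = 0.0
    elif b == 0.0:
        oz1_total = s0 - substrate
        oz2_total = 0.0
    else:
        oz1_total = s0 * a / (a - b) * (math.exp(-b * days) - math.exp(-a * days))
        oz2_total = s0 - substrate - oz1_total
    # Epoxidation is capped at t=0+; epoxides with residual C=C ozonolyze on.
    epoxide = e0 * math.exp(-(d - 1) * k * days)
    epoxide_lost = e0 - epoxide

    weights = _omega_weights(species, profile)
    if species.lipid_class == "SQ":
        # SQ ozonolysis products are volatile: they leave the spectrum.
        return SpeciesPools(
            species, abundance, substrate, epoxide, epoxide_lost,
            {}, {}, oz1_total + oz2_total,
        )
    ozonide = {w: oz1_total * f for w, f in weights.items()}
    ozonide2: dict[tuple[int, int], float] = {}
    if oz2_total > 0.0:
        for w1, f1 in weights.items():
            for w2, f2 in weights.items():
                if w2 < w1:
                    continue
                frac = f1 * f2 * (2.0 if w1 != w2 else 1.0)
                ozonide2[(w1, w2)] = ozonide2.get((w1, w2), 0.0) + oz2_total * frac
    return SpeciesPools(
        species, abundance, substrate, epoxide, epoxide_lost,
        ozonide, ozonide2, 0.0,
    )


def age_profile(
    profile: SebumProfile, days: float, params: AgingParams | None = None
) -> dict[LipidSpecies, SpeciesPools]:
    """Evolve every species' abundance for ``days`` of ambient aging.

    Closed-form solution of the sequential first-order chain substrate ->
    ozonide -> double-ozonide, with the instantaneous monolayer epoxide cap
    applied at t=0+.  Mass balance per species holds to ~1e-12.
    """
    if days < 0:
        raise ValueError("days must be >= 0")
    params = params or AgingParams()
    return {
        sp: _species_pools(sp, ab, days, params, profile)
        for sp, ab in profile.species.items()
    }


# ---------------------------------------------------------------------------
# Measurement forward model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _IonEvent:
    composition: ElementalComposition
    abundance: float
    source: str
    product_tag: str
    omega: str
    adduct: str
    annotatable: bool
    isotope: int = 0


def _sodiate(neutral: ElementalComposition) -> ElementalComposition:
    return neutral + _NA


def _disodiate(neutral: ElementalComposition) -> ElementalComposition:
    return neutral - _H + 2 * _NA


def _chain(omega: int) -> ElementalComposition:
    return ElementalComposition(n_C=omega, n_H=2 * omega)


def _base_events(
    pools: Mapping[LipidSpecies, SpeciesPools], params: AgingParams
) -> list[_IonEvent]:
    events: list[_IonEvent] = []

    def emit(neutral, ab, source, tag, omega="", disodiated=False, annotatable=True):
        if ab <= 0.0:
            return
        ion = _disodiate(neutral) if disodiated else _sodiate(neutral)
        adduct = "2Na" if disodiated else "Na"
        events.append(
            _IonEvent(ion, ab, source, tag, omega, adduct, annotatable)
        )

    p_soz = params.branch_intact_ozonide
    p_a = params.branch_insource_a
    p_bc = params.branch_insource_bc
    f_di = params.frac_criegee_disodiated

    for sp, pool in pools.items():
        cls = sp.lipid_class
        name = species_name(sp)
        neutral = compose_lipid(sp)
        is_fa = cls == "FA"
        emit(neutral, pool.substrate, name, "substrate", disodiated=is_fa)
        if pool.epoxide > 0.0:
            emit(neutral + _O, pool.epoxide, name, "E", disodiated=is_fa)
        for w, ab in pool.ozonide.items():
            head = neutral - _chain(w)
            # Intact secondary ozonide survives the source (not in the class
            # list -> not annotatable).
            emit(neutral + 3 * _O, ab * p_soz, name, "SOZ", str(w),
                 annotatable=False)
            # In-source A: head aldehyde + the released tail acid (FA w:0).
            emit(head + _O, ab * p_a, name, "A", str(w), disodiated=is_fa)
            emit(_chain(w) + 2 * _O, ab * p_a, name, "tail_acid", str(w),
                 disodiated=True)
            # In-source Criegee head: sodiated B/C isomers, partly detected
            # as the disodiated acid (product C).
            emit(head + 2 * _O, ab * p_bc * (1.0 - f_di), name, "B/C", str(w))
            emit(head + 2 * _O, ab * p_bc * f_di, name, "B/C", str(w),
                 disodiated=True)
        for (w1, w2), ab in pool.ozonide2.items():
            omega = f"{w1}+{w2}"
            head = neutral - _chain(w1) - _chain(w2)
            emit(neutral + 6 * _O, ab * p_soz, name, "SOZ2", omega,
                 annotatable=False)
            emit(head + 2 * _O, ab * p_a, name, "AA", omega)
            emit(_chain(w1) + 2 * _O, ab * p_a, name, "tail_acid", str(w1),
                 disodiated=True)
            emit(_chain(w2) + 2 * _O, ab * p_a, name, "tail_acid", str(w2),
                 disodiated=True)
    return events


def _expand_events(
    base: Iterable[_IonEvent], params: AgingParams
) -> list[_IonEvent]:
    """Add potassium twins and 13C isotopologues."""
    r = params.c13_abundance
    ratio = r / (1.0 - r)
    expanded: list[_IonEvent] = []
    with_twins: list[_IonEvent] = []
    for event in base:
        with_twins.append(event)
        if (
            params.k_adduct_fraction > 0.0
            and event.annotatable
            and event.composition.n_Na >= 1
        ):
            with_twins.append(
                replace(
                    event,
                    composition=event.composition.replace_na_with_k(),
                    abundance=event.abundance * params.k_adduct_fraction,
                    adduct=event.adduct + "/K",
                )
            )
    for event in with_twins:
        expanded.append(event)
        n = event.composition.n_C
        m1 = event.abundance * n * ratio
        m2 = event.abundance * math.comb(n, 2) * ratio * ratio if n >= 2 else 0.0
        comp = event.composition
        for iso, ab in ((1, m1), (2, m2)):
            if ab <= 0.0:
                continue
            iso_comp = ElementalComposition(
                comp.n_C - iso, comp.n_H, comp.n_O, comp.n_Na, comp.n_K,
                comp.n_13C + iso,
            )
            expanded.append(
                replace(
                    event,
                    composition=iso_comp,
                    abundance=ab,
                    annotatable=False,
                    isotope=iso,
                )
            )
    return expanded


@dataclass(frozen=True)
class SimulatedSample:
    """A rendered spectrum with its ground-truth provenance table."""

    peaks: PeakList
    truth: pd.DataFrame


def render_spectrum(
    pools: Mapping[LipidSpecies, SpeciesPools],
    params: AgingParams | None = None,
    seed: int | np.random.Generator = 0,
    sample_id: str = "sample",
    age_days: float = 0.0,
    replicate: int = 1,
    deposition_factor: float = 1.0,
) -> SimulatedSample:
    """Render aged pools into a centroid spectrum plus truth table.

    Deterministic for a given seed.  The truth table records, per emitted
    ion event, the jittered event m/z, the merged peak m/z it ended up in,
    the ion formula, the source species and product tag, the ω position(s),
    adduct, isotopologue index, whether the ion is expected in the
    annotation target list (``annotatable``), and the size of the merged
    peak cluster.
    """
    params = params or AgingParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    events = _expand_events(_base_events(pools, params), params)

    scale = params.base_scale * deposition_factor
    kept: list[tuple[float, float, _IonEvent]] = []
    cv = params.intensity_cv
    for event in events:
        expected = event.abundance * scale
        if expected < params.min_intensity:
            continue
        mz = ion_mz(event.composition, 1)
        if not params.mz_range[0] <= mz <= params.mz_range[1]:
            continue
        jitter = rng.normal(0.0, params.mz_jitter_ppm) * 1e-6 if params.mz_jitter_ppm else 0.0
        noisy_mz = mz * (1.0 + jitter)
        intensity = expected
        if cv > 0.0:
            intensity *= math.exp(rng.normal(-0.5 * cv * cv, cv))
        kept.append((noisy_mz, intensity, event))

    noise_rows: list[tuple[float, float]] = []
    for _ in range(params.n_noise_peaks):
        mz = rng.uniform(*params.mz_range)
        intensity = rng.exponential(params.noise_floor)
        noise_rows.append((float(mz), float(intensity)))

    all_rows: list[tuple[float, float, _IonEvent | None]] = [
        *kept,
        *[(mz, inten, None) for mz, inten in noise_rows],
    ]
    all_rows.sort(key=lambda row: row[0])

    # Merge events closer than merge_tol_da into one centroid.
    clusters: list[list[tuple[float, float, _IonEvent | None]]] = []
    for row in all_rows:
        if clusters and row[0] - clusters[-1][-1][0] <= params.merge_tol_da:
            clusters[-1].append(row)
        else:
            clusters.append([row])

    peak_mz: list[float] = []
    peak_intensity: list[float] = []
    truth_rows: list[dict] = []
    for cluster in clusters:
        total = sum(inten for _, inten, _ in cluster)
        center = sum(mz * inten for mz, inten, _ in cluster) / total
        peak_mz.append(center)
        peak_intensity.append(total)
        for mz, inten, event in cluster:
            if event is None:
                source, tag, omega, adduct, annotatable, iso, formula = (
                    "noise", "noise", "", "", False, 0, ""
                )
            else:
                source, tag, omega, adduct, annotatable, iso = (
                    event.source, event.product_tag, event.omega,
                    event.adduct, event.annotatable, event.isotope,
                )
                formula = event.composition.formula()
            truth_rows.append(
                {
                    "peak_mz": center,
                    "event_mz": mz,
                    "intensity": inten,
                    "formula": formula,
                    "source": source,
                    "product_tag": tag,
                    "omega": omega,
                    "adduct": adduct,
                    "isotope": iso,
                    "annotatable": annotatable,
                    "cluster_size": len(cluster),
                }
            )

    peaks = PeakList(
        mz=np.asarray(peak_mz),
        intensity=np.asarray(peak_intensity),
        sample_id=sample_id,
        age_days=age_days,
        replicate=replicate,
        noise_level=params.noise_floor * deposition_factor,
    )
    truth = pd.DataFrame(truth_rows)
    return SimulatedSample(peaks=peaks, truth=truth)


#: Ages analysed in quadruplicate in the reference aging design.
QUADRUPLICATE_AGES = (0, 3, 7)


def generate_timecourse(
    ages: Sequence[float] = (0, 1, 3, 5, 7),
    replicates: int = 4,
    seed: int = 0,
    profile: SebumProfile | None = None,
    params: AgingParams | None = None,
) -> list[SimulatedSample]:
    """Simulate a full aging time course with replicate structure.

    Ages 0/3/7 receive ``replicates`` replicates, other ages a single one
    (mirroring the quadruplicate design of the reference aging experiment).
    Each replicate gets its own lognormal deposition factor.  Fixed seeds
    give byte-identical output.
    """
    params = params or AgingParams()
    profile = profile or default_sebum_profile(seed=0)
    plan = [
        (age, rep)
        for age in ages
        for rep in range(
            1, (replicates if age in QUADRUPLICATE_AGES else 1) + 1
        )
    ]
    children = np.random.SeedSequence(seed).spawn(len(plan))
    samples: list[SimulatedSample] = []
    pools_by_age: dict[float, dict] = {}
    for (age, rep), child in zip(plan, children):
        if age not in pools_by_age:
            pools_by_age[age] = age_profile(profile, age, params)
        rng = np.random.default_rng(child)
        deposition = float(math.exp(rng.normal(0.0, params.deposition_cv)))
        samples.append(
            render_spectrum(
                pools_by_age[age],
                params,
                seed=rng,
                sample_id=f"day{age:g}_rep{rep}",
                age_days=float(age),
                replicate=rep,
                deposition_factor=deposition,
            )
        )
    return samples
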