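"""In-silico library of sebum lipids and their ambient oxidation products.

Sebaceous fingerprints are dominated by triacylglycerols (TG) with squalene
(SQ), wax esters (WE), free fatty acids (FA) and diacylglycerols (DG).
Ambient ozone cleaves carbon-carbon double bonds via a primary ozonide that
rearranges to a relatively stable secondary ozonide; during MALDI the ozonide
fragments in-source into a head aldehyde (product A) and the isomeric
Criegee/carboxylic-acid products (B or C), releasing a short-chain tail.
Ambient singlet oxygen additionally epoxidizes double bonds (product E: one
extra O, no chain loss, DBE conserved — the oxirane ring replaces the C=C).

Cleaving a double bond at the ω-n position (n carbons from the methyl
terminus) removes exactly CnH2n from the head product, so an ω-10 cleavage of
TG 47:1 yields the TG(A) 37:0 head aldehyde, and the released tail appears as
decanoic acid (FA 10:0), detected as its disodiated ion.

:func:`build_target_list` enumerates these products for configurable substrate
ranges into a sorted, de-duplicated list of theoretical sodiated (and, for
carboxylic acids, disodiated) ions — the target list that spectra are
annotated against at ±2 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem import ElementalComposition, dbe, ion_mz, z_value

__all__ = [
    "LIPID_CLASSES",
    "ESTER_COUNT",
    "LipidSpecies",
    "OzonolysisProducts",
    "TargetEntry",
    "SubstrateRange",
    "TargetListConfig",
    "compose_lipid",
    "species_name",
    "ozonolysis_products",
    "double_ozonolysis_products",
    "epoxidation_product",
    "build_target_list",
    "targets_to_frame",
    "write_target_list",
    "read_target_list",
]

LIPID_CLASSES = ("FA", "DG", "TG", "WE", "SQ")

#: Ester (carbonyl) groups contributed by the lipid backbone; SQ carries six
#: C=C instead and is handled as a single species.
ESTER_COUNT = {"FA": 1, "WE": 1, "DG": 2, "TG": 3}

#: Oxygens in the neutral substrate formula.
SUBSTRATE_OXYGENS = {"FA": 2, "WE": 2, "DG": 5, "TG": 6}

_O = ElementalComposition(n_O=1)

PRODUCT_TAGS = ("substrate", "A", "B/C", "AA", "E")
_TAG_RANK = {tag: i for i, tag in enumerate(PRODUCT_TAGS)}


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid: class, total acyl/chain carbons, total C=C count.

    ``db_positions`` optionally pins each double bond to an ω-position
    (carbons counted from the methyl terminus, ω >= 2).
    """

    lipid_class: str
    n_acyl_C: int
    n_db: int = 0
    db_positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.n_acyl_C < 1:
            raise ValueError("n_acyl_C must be >= 1")
        if self.n_db < 0:
            raise ValueError("n_db must be >= 0")
        if self.db_positions is not None:
            if len(self.db_positions) != self.n_db:
                raise ValueError("db_positions length must equal n_db")
            if any(w < 2 for w in self.db_positions):
                raise ValueError("omega positions must be >= 2")
        if self.lipid_class == "SQ" and (self.n_acyl_C, self.n_db) != (30, 6):
            raise ValueError("SQ is the single species C30H50 (30 carbons, 6 C=C)")


SQUALENE = LipidSpecies("SQ", 30, 6)


def species_name(species: LipidSpecies) -> str:
    """Shorthand name, e.g. ``"TG 48:0"`` or ``"SQ"``."""
    if species.lipid_class == "SQ":
        return "SQ"
    return f"{species.lipid_class} {species.n_acyl_C}:{species.n_db}"


def compose_lipid(species: LipidSpecies) -> ElementalComposition:
    """Neutral elemental composition from standard lipid stoichiometry.

    FA/WE n:d -> CnH(2n-2d)O2; DG n:d -> glycerol + 2 acyls - 2 H2O;
    TG n:d -> glycerol + 3 acyls - 3 H2O; SQ -> C30H50.  ``n`` counts acyl
    (chain) carbons only; the DG/TG formula carbon number is ``n + 3``.
    """
    n, d = species.n_acyl_C, species.n_db
    cls = species.lipid_class
    if cls in ("FA", "WE"):
        return ElementalComposition(n_C=n, n_H=2 * n - 2 * d, n_O=2)
    if cls == "DG":
        return ElementalComposition(n_C=n + 3, n_H=2 * n - 2 * d + 4, n_O=5)
    if cls == "TG":
        return ElementalComposition(n_C=n + 3, n_H=2 * n - 2 * d + 2, n_O=6)
    if cls == "SQ":
        return ElementalComposition(n_C=30, n_H=50)
    raise ValueError(f"unknown lipid class {cls!r}")  # pragma: no cover


def _chain_delta(omega: int) -> ElementalComposition:
    return ElementalComposition(n_C=omega, n_H=2 * omega)


@dataclass(frozen=True)
class OzonolysisProducts:
    """Neutral compositions from one ozonolysis event at a given ω."""

    head_aldehyde: ElementalComposition   # product A
    head_criegee: ElementalComposition    # products B/C (isomeric acid)
    tail_acid: ElementalComposition       # product C tail, an FA ω:0
    tail_aldehyde: ElementalComposition   # volatile, rarely observed
    head_acyl_carbons: int
    head_residual_db: int


def ozonolysis_products(species: LipidSpecies, omega: int) -> OzonolysisProducts:
    """Products of cleaving one C=C at the ω position.

    The head keeps the backbone: A = substrate - CωH2ω + O (aldehyde), B/C =
    substrate - CωH2ω + 2O (carbonyl oxide / carboxylic acid isomers).  The
    released tail is CωH2ωO2 (acid) or CωH2ωO (aldehyde).  One C=C is
    consumed; DBE of the head is unchanged (C=O replaces C=C).
    """
    if species.n_db < 1:
        raise ValueError(f"{species_name(species)} has no C=C to ozonolyze")
    if not 2 <= omega < species.n_acyl_C:
        raise ValueError(
            f"omega={omega} outside valid range [2, {species.n_acyl_C}) "
            f"for {species_name(species)}"
        )
    substrate = compose_lipid(species)
    delta = _chain_delta(omega)
    return OzonolysisProducts(
        head_aldehyde=substrate - delta + _O,
        head_criegee=substrate - delta + 2 * _O,
        tail_acid=delta + 2 * _O,
        tail_aldehyde=delta + _O,
        head_acyl_carbons=species.n_acyl_C - omega,
        head_residual_db=species.n_db - 1,
    )


def double_ozonolysis_products(
    species: LipidSpecies, omegas: tuple[int, int]
) -> ElementalComposition:
    """AA product: two sequential head-aldehyde cleavages on distinct chains.

    Only multi-chain substrates (DG, WE, TG) undergo a detectable second
    ozonolysis; the result applies the A delta (-CωH2ω +O) once per site.
    """
    if species.lipid_class not in ("DG", "WE", "TG"):
        raise ValueError(
            f"double ozonolysis is only enumerated for DG/WE/TG, "
            f"not {species.lipid_class}"
        )
    if species.n_db < 2:
        raise ValueError(f"{species_name(species)} needs >= 2 C=C")
    w1, w2 = omegas
    if min(w1, w2) < 2 or w1 + w2 >= species.n_acyl_C:
        raise ValueError(f"omega pair {omegas} incompatible with chain carbons")
    substrate = compose_lipid(species)
    return substrate - _chain_delta(w1) - _chain_delta(w2) + 2 * _O


def epoxidation_product(species: LipidSpecies) -> ElementalComposition:
    """Epoxide (product E): substrate + O; C, H and DBE unchanged.

    One C=C becomes an oxirane ring, so ``TG X:1`` is named ``TG(E) X:0``
    (residual unsaturation drops by one).
    """
    if species.n_db < 1:
        raise ValueError(f"{species_name(species)} has no C=C to epoxidize")
    return compose_lipid(species) + _O


# ---------------------------------------------------------------------------
# Target list construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetEntry:
    """One theoretical ion of the annotation target list."""

    label: str
    composition: ElementalComposition
    mz: float
    substrate_class: str
    product_tag: str
    carbon_number: int
    dbe: int
    z: int
    n_O: int
    n_Na: int
    n_K: int
    labels: tuple[str, ...] = ()

    @property
    def class_key(self) -> tuple[int, int, int, int]:
        """(O, Na, K, Z): the heteroatom class this ion belongs to."""
        return (self.n_O, self.n_Na, self.n_K, self.z)


@dataclass(frozen=True)
class SubstrateRange:
    """Formula carbon-number and DBE range enumerated for one lipid class."""

    c_min: int
    c_max: int
    dbe_min: int
    dbe_max: int

    def __post_init__(self) -> None:
        if self.c_min > self.c_max or self.dbe_min > self.dbe_max:
            raise ValueError("empty substrate range")


def _default_substrates() -> dict[str, SubstrateRange]:
    # Formula carbon numbers c (DG/TG include the glycerol C3); DBE counts the
    # backbone esters plus C=C, so e.g. TG DBE 3-6 spans 0-3 double bonds.
    return {
        "FA": SubstrateRange(8, 26, 1, 2),
        "DG": SubstrateRange(26, 44, 2, 4),
        "WE": SubstrateRange(26, 46, 1, 3),
        "TG": SubstrateRange(40, 60, 3, 6),
    }


@dataclass(frozen=True)
class TargetListConfig:
    substrates: Mapping[str, SubstrateRange] = field(
        default_factory=_default_substrates
    )
    omega_range: tuple[int, int] = (8, 11)
    allow_one_K_substitution: bool = True
    include_double_ozonolysis: bool = True
    include_squalene: bool = True
    include_tail_aldehyde: bool = False
    mz_range: tuple[float, float] = (100.0, 1200.0)

    def __post_init__(self) -> None:
        if not self.substrates:
            raise ValueError("no substrate classes configured")
        if self.omega_range[0] > self.omega_range[1] or self.omega_range[0] < 2:
            raise ValueError("invalid omega range")
        if not 0 < self.mz_range[0] < self.mz_range[1]:
            raise ValueError("invalid m/z range")


def _neutral_products(
    cls: str, c: int, d: int, config: TargetListConfig
) -> Iterable[tuple[str, ElementalComposition, int]]:
    """Yield (tag, neutral composition, formula carbons) per product."""
    acyl = c - 3 if cls in ("DG", "TG") else c
    species = LipidSpecies(cls, acyl, d)
    substrate = compose_lipid(species)
    yield "substrate", substrate, c
    if d < 1:
        return
    yield "E", epoxidation_product(species), c
    w_lo, w_hi = config.omega_range
    for w in range(w_lo, w_hi + 1):
        # Head must keep >= 2 chain carbons besides the cleavage site.
        if w > acyl - 2:
            continue
        prods = ozonolysis_products(species, w)
        yield "A", prods.head_aldehyde, c - w
        yield "B/C", prods.head_criegee, c - w
        if config.include_tail_aldehyde:
            yield "A", prods.tail_aldehyde, w
    if (
        config.include_double_ozonolysis
        and d >= 2
        and cls in ("DG", "WE", "TG")
    ):
        for w1 in range(w_lo, w_hi + 1):
            for w2 in range(w1, w_hi + 1):
                if w1 + w2 > acyl - 2:
                    continue
                aa = double_ozonolysis_products(species, (w1, w2))
                yield "AA", aa, c - w1 - w2


_NA = ElementalComposition(n_Na=1)
_H = ElementalComposition(n_H=1)


def _acid_bearing(cls: str, tag: str) -> bool:
    # Entries retaining a free carboxyl: every FA-derived form and, for the
    # multi-chain substrates, the acid isomer of the Criegee head (product C).
    if cls == "FA":
        return True
    return tag == "B/C"


def build_target_list(config: TargetListConfig | None = None) -> list[TargetEntry]:
    """Enumerate the theoretical heteroatom-class target list, sorted by m/z.

    Every substrate/product composition is emitted as its [M+Na]+ ion;
    carboxylic-acid analytes additionally as the disodiated [M-H+2Na]+ ion
    (sodium adduct of the sodium carboxylate) — the disodiated Criegee head is
    labelled "X(C)".  With ``allow_one_K_substitution`` each Na-bearing
    entry gains a twin with one Na replaced by K (+15.9740 Da).  Duplicate ion
    compositions (e.g. an isomeric TG(A)/TG(E) pair, or FA vs WE substrates)
    are collapsed into one entry carrying all labels.
    """
    config = config or TargetListConfig()
    raw: list[TargetEntry] = []

    def emit(label, ion, cls, tag, c):
        mz = ion_mz(ion, 1)
        if not config.mz_range[0] <= mz <= config.mz_range[1]:
            return
        neutral_parent = ion - _NA if ion.n_Na else ion - ElementalComposition(n_K=1)
        raw.append(
            TargetEntry(
                label=label,
                composition=ion,
                mz=mz,
                substrate_class=cls,
                product_tag=tag,
                carbon_number=ion.total_carbon,
                dbe=dbe(neutral_parent),
                z=z_value(neutral_parent),
                n_O=ion.n_O,
                n_Na=ion.n_Na,
                n_K=ion.n_K,
            )
        )

    def emit_with_adducts(cls, tag, neutral, c):
        base = cls if tag == "substrate" else f"{cls}({tag})"
        emit(base, neutral + _NA, cls, tag, c)
        if _acid_bearing(cls, tag):
            di_label = f"{cls}(C)" if (tag == "B/C" and cls != "FA") else base
            emit(di_label, neutral - _H + 2 * _NA, cls, tag, c)

    for cls, rng in config.substrates.items():
        if cls == "SQ":
            continue
        esters = ESTER_COUNT[cls]
        for c in range(rng.c_min, rng.c_max + 1):
            for dbe_val in range(rng.dbe_min, rng.dbe_max + 1):
                d = dbe_val - esters
                if d < 0:
                    continue
                acyl = c - 3 if cls in ("DG", "TG") else c
                if acyl < 1 or 2 * acyl - 2 * d < 2:
                    continue
                for tag, neutral, pc in _neutral_products(cls, c, d, config):
                    emit_with_adducts(cls, tag, neutral, pc)

    if config.include_squalene:
        emit_with_adducts("SQ", "substrate", compose_lipid(SQUALENE), 30)
        emit_with_adducts("SQ", "E", epoxidation_product(SQUALENE), 30)

    if config.allow_one_K_substitution:
        for entry in list(raw):
            if entry.n_Na < 1:
                continue
            ion = entry.composition.replace_na_with_k()
            raw.append(
                replace(
                    entry,
                    label=entry.label + "+K",
                    composition=ion,
                    mz=ion_mz(ion, 1),
                    n_Na=ion.n_Na,
                    n_K=ion.n_K,
                )
            )

    # Collapse duplicate ion compositions; keep the highest-priority label.
    def priority(e: TargetEntry):
        return (e.n_K, _TAG_RANK[e.product_tag], e.n_O, e.label)

    by_comp: dict[ElementalComposition, list[TargetEntry]] = {}
    for entry in raw:
        by_comp.setdefault(entry.composition, []).append(entry)

    merged: list[TargetEntry] = []
    for entries in by_comp.values():
        entries.sort(key=priority)
        primary = entries[0]
        if not config.mz_range[0] <= primary.mz <= config.mz_range[1]:
            continue
        labels = tuple(dict.fromkeys(e.label for e in entries))
        merged.append(replace(primary, labels=labels))

    merged.sort(key=lambda e: e.mz)
    return merged


_TSV_COLUMNS = [
    "label", "formula", "mz_theoretical", "c", "DBE", "Z",
    "O", "Na", "K", "product_tag", "substrate", "all_labels",
]


def targets_to_frame(targets: Sequence[TargetEntry]) -> pd.DataFrame:
    rows = [
        {
            "label": t.label,
            "formula": t.composition.formula(),
            "mz_theoretical": round(t.mz, 6),
            "c": t.carbon_number,
            "DBE": t.dbe,
            "Z": t.z,
            "O": t.n_O,
            "Na": t.n_Na,
            "K": t.n_K,
            "product_tag": t.product_tag,
            "substrate": t.substrate_class,
            "all_labels": ";".join(t.labels or (t.label,)),
        }
        for t in targets
    ]
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_target_list(targets: Sequence[TargetEntry], path) -> None:
    targets_to_frame(targets).to_csv(path, sep="\t", index=False)


def read_target_list(path) -> list[TargetEntry]:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"target list missing columns: {sorted(missing)}")
    targets = []
    for row in frame.itertuples(index=False):
        comp = ElementalComposition.from_formula(row.formula)
        targets.append(
            TargetEntry(
                label=row.label,
                composition=comp,
                mz=ion_mz(comp, 1),
                substrate_class=row.substrate,
                product_tag=row.product_tag,
                carbon_number=int(row.c),
                dbe=int(row.DBE),
                z=int(row.Z),
                n_O=int(row.O),
                n_Na=int(row.Na),
                n_K=int(row.K),
                labels=tuple(str(row.all_labels).split(";")),
            )
        )
    targets.sort(key=lambda e: e.mz)
    return targets
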