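# Methods

`kmdprint` analyses the ambient oxidation chemistry of sebaceous fingerprint
lipids in high-resolution MALDI spectra, using Kendrick-mass-defect (KMD)
coordinates to organize the data and an enumerated product library to assign
heteroatom classes. This note documents the model, its parameters, the
numerical choices, and what the bundled simulator does and does not emulate.

## Mass arithmetic and conventions

All masses are monoisotopic sums over a pinned atomic-mass table (H
1.00782503207, C 12, ¹³C 13.00335483507, O 15.99491461956, Na 22.9897692809,
K 38.96370668 Da; electron 0.00054857991 Da). Ion m/z subtracts the electron
mass — 0.7 ppm at m/z 800, comparable to the ±2 ppm annotation tolerance, so
it is not negligible. With this table the two reference ions reproduce at
printed precision: sodiated squalene [C30H50 + Na]⁺ = 433.3805 and the
disodiated decanoate ion C10H19O2Na2⁺ = 217.117.

Double-bond equivalents and the hydrogen-deficiency integer Z are properties
of the *neutral parent*: the cationizing Na/K is stripped and a salt-forming
Na/K (the sodium of a sodium carboxylate) counts as one hydrogen, so that

* saturated TGs have DBE 3 (three ester carbonyls),
* the monounsaturated sodiated-TG class C_cH_{2c−Z}O₆Na has DBE 4,
* the disodiated fatty-acid class C_cH_{2c−Z}O₂Na₂ has DBE 1,

and `Z = 2·(DBE − 1)` throughout. Note that a fully saturated acyclic
alkane sits at Z = −2 (DBE 0); Z = 0 corresponds to the one-ester baseline.

## Kendrick coordinates

KM = m/z · 14 / 14.01565006…, with the CH₂ base mass computed from the same
atomic-mass table. KMD = round(KM) − KM with **round-half-up**; this sign
convention places the sebum-lipid region at positive KMD 0.05–0.35 (part of
the literature instead uses KM − floor(KM); the conversion is a sign flip
plus an integer offset). The rounding rule at the exact .5 boundary is
half-up; no physical species in range is affected. One degree of
unsaturation offsets parallel homologous series by the Kendrick-rescaled H₂
mass minus 2 = 0.013399… ≈ 0.0134.

Homologous-series grouping joins two centroids when their KMD differ by at
most 0.0005 (≈2 ppm at m/z 250 in KMD units) *and* their m/z gap is an
integer multiple of the CH₂ mass within ±2 ppm; series are the transitive
closure of that relation (union-find over a KMD-sorted sweep, verified
against a brute-force pairwise oracle in the tests).

## The oxidation-product library

Substrate classes FA, DG, TG, WE (homologous) plus squalene as a single
species (C30H50; no homologous series, and its oxidation products are
volatile). Standard stoichiometry: FA/WE n:d = C_nH_{2n−2d}O₂; DG n:d =
glycerol + 2 acyls − 2 H₂O = C_{n+3}H_{2n−2d+4}O₅; TG n:d =
C_{n+3}H_{2n−2d+2}O₆.

Ozonolysis of a C=C at position ω (counted from the methyl terminus)
produces, per event:

| product | composition delta (head keeps the backbone) |
| --- | --- |
| A (head aldehyde) | substrate − C_ωH_{2ω} + O |
| B/C (head Criegee/acid isomers) | substrate − C_ωH_{2ω} + 2O |
| tail acid (an FA ω:0) | C_ωH_{2ω}O₂ |
| tail aldehyde (volatile) | C_ωH_{2ω}O |

Head DBE is conserved (C=O replaces C=C). Double (sequential) ozonolysis is
enumerated for the multi-chain substrates DG/WE/TG only, applying the A
delta once per site. Epoxidation (product E) adds one O with C, H and DBE
unchanged; consequently every E member falls in the heteroatom class with
one more oxygen and the same Z as its substrate — TG(E) shares the O₇/DBE-4
class with TG(A), and the two populations are separated by mass region, not
by formula.

The default target list enumerates formula carbon numbers FA 8–26 (DBE 1–2),
DG 26–44 (2–4), WE 26–46 (1–3), TG 40–60 (3–6), ω 8–11, retained over m/z
100–1200. The exact ranges are a reconstruction from the ester-count logic
and the plotted spectral range, and are fully config-exposed. Every
composition is emitted as [M+Na]⁺; carboxylic-acid analytes (all FA-derived
forms and the acid isomer of the Criegee head, labelled "X(C)") additionally
as the disodiated [M−H+2Na]⁺; and each Na-bearing entry gains a potassium
twin (one Na→K, +15.9740 Da). Duplicate ion compositions — isomers such as
TG(A)/TG(E) pairs or FA/WE substrates with equal chain carbons — are
collapsed into a single multi-label entry. Tail aldehydes are enumerated
only behind a flag (they are volatile and essentially absent from MALDI
spectra). Hydroxyl isomers of epoxides are isobaric at this resolution and
are not separate entries.

## Annotation

Peaks are assigned to the minimum-|ppm| target within ±2 ppm via binary
search over the m/z-sorted list. Exact-tie breaking prefers Na over K
adducts, substrates over products, then lower oxygen count (potassium
adducts are minor and must not displace the sodium interpretation).
Flags:

* **Type-II isotopic risk** — the M+2 ¹³C₂ isotopologue of a lipid with one
  more double bond lies only |2·(¹³C−¹²C) − m(H₂)| = 0.0089 Da below the
  assigned monoisotopic peak. An assignment is flagged when a peak found
  within ±0.012 Da of (m/z − 2·1.003355) has an expected binomial M+2
  contribution of at least 20 % of the assigned intensity (carbon count from
  its own annotation, else the lipid-like estimate m/z / 15). The 20 %
  threshold and the window are this package's choices.
* **multi-class ambiguity** — the assigned composition carries several class
  labels or another class lies within tolerance.

Class intensity profiles sum assigned intensity per carbon number for one
(O, Na, K, DBE) class. The bimodal split lays the profile on a dense carbon
grid, smooths with a 3-point moving average, finds local maxima, and — when
at least two exist — splits at the smoothed minimum between the two largest.
Profiles with fewer than 5 members are never split. The split method is this
package's design; the low-mass mode of the shared O₇ family is the
ozonolysis-aldehyde population, the high-mass mode the epoxide population,
separated by roughly the 10-carbon ω-10 cleavage offset.

## Spectra, normalization, subtraction

Peak lists are plain centroid TSVs (`mz`, `intensity`; `#`-prefixed
metadata: sample id, age in days, replicate, noise level, normalization
state) that round-trip bit-exactly at six decimals. Duplicate m/z rows merge
by intensity sum with a warning. To cancel deposition differences, spectra
are normalized to the summed signal of annotated saturated-TG substrates
(DBE 3); the operation is idempotent and scale-invariant, and fails loudly
when no saturated TG is present. Subtraction (aged − fresh) pairs peaks
greedily by smallest ppm distance within ±2 ppm (the pairing rule is ours),
keeps unmatched peaks with the absent side at zero, and reports matched bins
at the midpoint m/z so that subtraction is exactly antisymmetric. S/N uses
the recorded noise level when present, else the median intensity — the
S/N > 30 display filter needs *some* noise definition and the source data's
is unknown.

## Aging markers

* **Epoxide ratios**: intensity(TG(E) c:r) / intensity(TG c:0) per acyl
  carbon count c, grouped by residual unsaturation r, averaged over a
  default carbon window of acyl C49–C54. The window is deliberately the
  high-mass range where no enumerated TG(A) isomer can share the epoxide
  composition (an aldehyde at formula carbon ≥ 52 would need a parent TG
  beyond the enumerated range); at lower carbon numbers the two populations
  genuinely overlap and only the profile split separates them.
* **FA profiles / FA 10:0 marker**: disodiated FA class intensities per
  chain length; the marker is FA 10:0 / FA 15:0 (FA 15:0 and 17:0 are the
  preferred normalizers — endogenous, age-stable, least contamination-prone).
  Missing peaks impute to zero (below detection) rather than dropping, so
  series stay aligned.
* Replicates aggregate as arithmetic mean ± 1 sd, no outlier rejection; sd
  is reported only for n ≥ 2. All markers are within-sample ratios and thus
  invariant to deposition amount.
* The epoxide-vs-Criegee comparison (`tg_epoxide_vs_criegee`) sums the TG
  O₇ sodiated classes at formula carbon ≥ 52 against the disodiated O₈
  TG(C) class over all carbons.

## The synthetic fingerprint simulator

The simulator is a forward model used to validate every stage; it is not a
calibrated kinetic model of real fingerprints.

**Composition** (defaults, normalized to sum 1): TGs with acyl C40–C56 and
0–3 C=C under a narrow Gaussian envelope centred at TG 48 (sd 2.5 carbons —
the abundant TGs occupy a ~10-carbon window, sodiated ions m/z ~770–900)
with abundance falling with unsaturation; abundant squalene; minor WE
(C30–C40) and DG (C30–C36); endogenous FAs 13:0–18:1 including sapienic acid
16:1. FA 10:0 starts at exactly zero. ω-position prior: ω-10 0.65, ω-9 0.15,
ω-8 and ω-11 0.10 each.

**Kinetics** (closed form, so mass balance is exact and output is
byte-deterministic):

* Epoxidation is an instantaneous, monolayer-capped conversion of 5 % of
  each unsaturated species at t = 0⁺ (encoding rapid surface epoxidation
  that then stops), not a competing rate.
* Ozonolysis is first order per C=C with a single ambient rate constant
  k = 0.5 /day (no rate is available for the real system; only relative
  trends are asserted anywhere). A species with d double bonds decays at
  d·k into a secondary-ozonide pool; for multi-chain substrates that pool
  reacts on at (d−1)·k into a double-ozonide pool. Epoxides with residual
  C=C decay at (d−1)·k into an unobserved sink. Ozonolysis flux splits
  across ω deterministically by the ω prior (equivalent in expectation to
  per-event sampling, and it preserves exact mass balance).
* Squalene's ozonolysis products are volatile and leave the spectrum.

**Measurement**: the ozonide pool is partitioned at render time into 60 %
intact secondary ozonide (substrate + 3O, deliberately *not* in the target
list), 25 % in-source aldehyde A plus the released disodiated tail acid, and
15 % in-source Criegee head (half sodiated B/C, half disodiated C). These
branching fractions are free parameters. Each ion gets Gaussian m/z jitter
(sd 0.5 ppm), lognormal intensity noise (cv 8 %), binomial ¹³C M+1/M+2
isotopologues (r = 0.0107), a 4 % potassium-adduct twin, and peaks within
0.001 Da merge into one centroid (the 0.0089 Da Type-II gap stays resolved).
150 uniform noise peaks (exponential intensities, floor 100 on a 10⁶ base
scale) and a lognormal per-replicate deposition factor (cv 0.2) complete the
spectrum. The truth table records every event's source, product tag, ω,
adduct, isotopologue index and merged-peak membership.

**Time course**: ages 0/1/3/5/7 days with quadruplicates at 0, 3 and 7 and
single samples at 1 and 5, replicating the reference aging design.

**Sparse-ozone preset**: k/5 and epoxide cap ×2, a qualitative mimic of a
low-ozone, UVA-lit chamber where singlet-oxygen epoxidation outruns
ozonolysis; under it the summed TG(E) signal exceeds the summed disodiated
TG(C) signal, while under ambient parameters it does not.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: spatial (imaging) structure, humidity/temperature
covariates, matrix and sputtering chemistry, volatile losses other than
squalene's, real (unknown) branching ratios and monolayer fractions,
contamination (e.g. the real-world FA 16:0 background), isotope fine
structure beyond ¹³C, and profile-mode peak shapes (everything is
centroided). Conclusions about real fingerprints rest on the analytic
reference values; the simulator demonstrates pipeline correctness and trend
recoverability under its stated assumptions.

## Numerical and scale choices

Problem sizes were chosen to keep the full suite fast: the default target
list has ~1.8 k entries, a rendered spectrum ~1.3 k centroids, and a full
time course 14 samples; the complete test suite runs in well under a minute.
Degenerate inputs fail explicitly: empty substrate ranges, inverted KMD/m-z
windows, unnormalized inputs to subtraction, a missing saturated-TG
denominator, omega positions incompatible with chain length, and non-integer
DBE (the signature of passing an ion where a neutral parent is required).
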