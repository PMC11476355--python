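"""Reference data for the twelve elementary steviol (diterpene) glycosides.

This module houses:

* the compound table — name, Hill formula, molecular weight, and the number
  of sugar rings attached on the C19 (ester/carboxyl) and C13 (tertiary
  alcohol) sides of the steviol aglycone;
* the band-assignment table mapping Raman shifts to vibrational modes of the
  glucose rings and the aglycone core, including the carbonyl-stretch class
  centers used to grade C19-side glycosylation;
* formula-mass computation from conventional atomic weights;
* a synthetic-spectrum generator that emulates measured spectra of pure
  compounds and of commercial-style blends: pseudo-Voigt bands at the
  assigned centers, glucose-ring band areas proportional to the total ring
  count, aglycone band areas constant per molecule, a carbonyl band placed at
  the class center of the C19 ring count, a smooth polynomial background and
  additive Gaussian noise.  The generator returns its injected truth (every
  band, plus the R1/R2 ratios and carbonyl centroid it implies) so that
  recovery by the fitting pipeline can be judged against ground truth.

No public spectral database of these compounds exists, so the generator is
the package's stand-in for measured data; its band *positions* are the
literature assignments while its *intensities* are plausible synthetic
choices, which is why intensity-ratio calibrations must be re-anchored on a
real instrument before quantitative use.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bandfit import Band, band_area
from .spectra_io import Spectrum

__all__ = [
    "CompoundRecord",
    "BandAssignment",
    "BlendSpec",
    "SynthTruth",
    "ATOMIC_WEIGHTS",
    "CARBONYL_CLASS_CENTERS",
    "LINKED_CARBONYL_THRESHOLD",
    "compounds",
    "get_compound",
    "mw_from_formula",
    "list_assignments",
    "synth_spectrum",
]

# Conventional atomic weights; these reproduce the reference molecular
# weights of all twelve glycosides to within 0.02 g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {"C": 12.0107, "H": 1.00794, "O": 15.9994}

#: Carbonyl-stretch class centers (cm^-1) keyed by the number of sugar rings
#: on the C19 side; "linked" is the extra carbonyl of the modified-C17/C16
#: configuration.  The 0-ring (1706), 1-ring (1719) and linked (1738) anchors
#: are literature values; the 2- and 3-ring centers are interpolations kept in
#: this one table so they can be re-anchored against a real instrument.
CARBONYL_CLASS_CENTERS: dict[object, float] = {
    0: 1706.0,
    1: 1719.0,
    2: 1728.0,
    3: 1733.0,
    "linked": 1738.0,
}

#: Fitted carbonyl sub-bands at or above this center are treated as the
#: linked-carbonyl class and excluded from the C19-glycosylation centroid.
LINKED_CARBONYL_THRESHOLD = 1734.0


@dataclass(frozen=True)
class CompoundRecord:
    """One elementary diterpene glycoside."""

    name: str
    formula: str
    mw: float  # g/mol
    rings_c19: int
    rings_c13: int
    note: str = ""

    @property
    def rings_total(self) -> int:
        return self.rings_c19 + self.rings_c13


# The reference table lists "Steviolbioside" twice; the second row's chemistry
# (a glucopyranosyl ester, C38H60O18, one C19-side ring) is that of
# Stevioside, under which name it is recorded here — see the note field.
_COMPOUNDS: tuple[CompoundRecord, ...] = (
    CompoundRecord("Dulcoside A", "C38H60O17", 788.87, 1, 2),
    CompoundRecord(
        "Stevioside", "C38H60O18", 804.87, 1, 2,
        note=(
            "Listed under the (duplicated) name 'Steviolbioside' in the source "
            "table; the formula and the glucopyranosyl-ester C19 ring identify "
            "it as Stevioside."
        ),
    ),
    CompoundRecord(
        "Steviolbioside", "C32H50O13", 642.73, 0, 2,
        note=(
            "Shows two carbonyl bands (1706 and 1738 cm^-1), interpreted as an "
            "additional linked carbonyl at the modified C17/C16 site."
        ),
    ),
    CompoundRecord("Rubusoside", "C32H50O13", 642.73, 1, 1),
    CompoundRecord("Rebaudioside A", "C44H70O23", 967.01, 1, 3),
    CompoundRecord("Rebaudioside B", "C38H60O18", 804.87, 0, 3),
    CompoundRecord(
        "Rebaudioside C", "C44H70O22", 951.01, 1, 3,
        note=(
            "One C13-side ring is rhamnose (a hydroxyl short of glucose); it "
            "still counts as a ring for the intensity-ratio scaling."
        ),
    ),
    CompoundRecord("Rebaudioside D", "C50H80O28", 1129.15, 2, 3),
    CompoundRecord("Rebaudioside E", "C44H70O23", 967.01, 2, 2),
    CompoundRecord("Rebaudioside F", "C43H68O22", 936.99, 1, 3),
    CompoundRecord("Rebaudioside M", "C56H90O33", 1291.29, 3, 3),
    CompoundRecord("Rebaudioside N", "C56H90O32", 1275.29, 3, 3),
)

_ALIASES = {"rebaudioside x": "rebaudioside m"}  # older name for Rebaudioside M
_BY_NAME = {c.name.lower(): c for c in _COMPOUNDS}


def compounds() -> tuple[CompoundRecord, ...]:
    """All twelve elementary-compound records, in library order."""
    return _COMPOUNDS


def get_compound(name: str) -> CompoundRecord:
    """Look up a compound case-insensitively (aliases accepted)."""
    key = name.strip().lower()
    key = _ALIASES.get(key, key)
    try:
        return _BY_NAME[key]
    except KeyError:
        valid = ", ".join(c.name for c in _COMPOUNDS)
        raise KeyError(f"unknown compound {name!r}; known compounds: {valid}") from None


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def mw_from_formula(formula: str) -> float:
    """Molecular weight (g/mol) of a C/H/O Hill-notation formula.

    Full precision is kept internally; round to 2 decimals only at report
    time.
    """
    if not formula or not formula.strip():
        raise ValueError("empty formula")
    pos, total = 0, 0.0
    text = formula.strip()
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r} near {text[pos:]!r}")
        pos = m.end()
        elem, count = m.group(1), int(m.group(2) or 1)
        if elem not in ATOMIC_WEIGHTS:
            raise ValueError(f"unsupported element {elem!r} in {formula!r}")
        if count <= 0:
            raise ValueError(f"non-positive count for {elem} in {formula!r}")
        total += count * ATOMIC_WEIGHTS[elem]
    if pos != len(text):
        raise ValueError(f"malformed formula {formula!r} near {text[pos:]!r}")
    return total


@dataclass(frozen=True)
class BandAssignment:
    """One row of the band-assignment table."""

    label: str
    moiety: str  # glucose_ring | aglycone_core | linked_carbonyl | extraneous
    center: float  # cm^-1
    window: tuple[float, float]


#: Glucose-ring mode windows: C-O/C-C stretching at 850-950 cm^-1 and
#: C-C-H / C-O-H bending at 1150-1250 cm^-1.  Carbonyl window 1690-1760.
ASSIGNMENTS: tuple[BandAssignment, ...] = (
    BandAssignment("O-C19=O bend", "aglycone_core", 740.0, (700.0, 780.0)),
    BandAssignment("adulterant marker (tentatively an artificial sweetener)",
                   "extraneous", 869.0, (850.0, 950.0)),
    BandAssignment("C5-O5 stretch (glucose ring)", "glucose_ring", 887.0, (850.0, 950.0)),
    BandAssignment("C11-C12 stretch", "aglycone_core", 898.0, (850.0, 950.0)),
    BandAssignment("C-C stretch (aglycone rings)", "aglycone_core", 1040.0, (1004.0, 1075.0)),
    BandAssignment("C6-O6-H bend (glucose ring)", "glucose_ring", 1192.0, (1150.0, 1250.0)),
    BandAssignment("H-C9-C11 stretch", "aglycone_core", 1204.0, (1150.0, 1250.0)),
    BandAssignment("C4-O4-H bend (glucose ring)", "glucose_ring", 1215.0, (1150.0, 1250.0)),
    BandAssignment("C16-C17 stretch", "aglycone_core", 1670.0, (1640.0, 1690.0)),
    BandAssignment("C19=O stretch", "aglycone_core", 1738.0, (1690.0, 1760.0)),
    BandAssignment("C16=O stretch (linked carbonyl)", "linked_carbonyl",
                   CARBONYL_CLASS_CENTERS["linked"], (1690.0, 1760.0)),
)


def list_assignments(moiety: str | None = None) -> list[BandAssignment]:
    """Assignment rows in stable order, optionally filtered by moiety."""
    if moiety is None:
        return list(ASSIGNMENTS)
    known = {"glucose_ring", "aglycone_core", "linked_carbonyl", "extraneous"}
    if moiety not in known:
        raise ValueError(f"unknown moiety {moiety!r}; expected one of {sorted(known)}")
    return [a for a in ASSIGNMENTS if a.moiety == moiety]


# ---------------------------------------------------------------------------
# Synthetic-spectrum generator
# ---------------------------------------------------------------------------

#: Per-molecule areal intensities of aglycone-core bands (arbitrary units x
#: cm^-1); constant across compounds because every glycoside carries exactly
#: one steviol core.
AGLYCONE_BAND_AREAS: dict[float, float] = {
    740.0: 0.60,
    898.0: 1.00,
    1040.0: 0.80,
    1204.0: 1.00,
    1670.0: 0.50,
}

#: Areal intensity contributed by each sugar ring to the glucose-ring bands.
GLUCOSE_BAND_AREAS_PER_RING: dict[float, float] = {
    887.0: 0.35,
    1192.0: 0.20,
    1215.0: 0.25,
}

#: Per-molecule areal intensity of the C19 carbonyl stretch.
CARBONYL_BAND_AREA = 0.70

#: Extra linked-carbonyl (1738 cm^-1) area injected for Steviolbioside,
#: reproducing its two-band carbonyl anomaly.
STEVIOLBIOSIDE_LINKED_AREA = 0.50

DEFAULT_FWHM = 8.0  # cm^-1, typical of the deconvoluted sub-bands
DEFAULT_ETA = 0.5

#: Default additive noise (a.u.).  The strongest generated band peaks near
#: 0.1 a.u. before normalization, so this is ~0.5% of the maximum signal —
#: the SNR regime of well-averaged high-resolution Raman acquisitions.
DEFAULT_NOISE_SIGMA = 0.0005

#: Default axis: 150-2150 cm^-1 sampled every 0.5 cm^-1 (the generator's
#: sampling choice, matching the order of the stated spectral resolution).
DEFAULT_AXIS = (150.0, 2150.0, 0.5)


@dataclass
class BlendSpec:
    """Recipe for a synthetic commercial-style blend.

    components are (compound name, weight fraction) pairs whose fractions are
    positive and sum to 1.  ``baseline`` holds polynomial coefficients
    (constant first) evaluated in the scaled coordinate u = (nu - nu_min) /
    (nu_max - nu_min) in [0, 1].  ``extra_bands`` allows injecting bands that
    do not belong to any steviol assignment (e.g. an adulterant marker at
    869 cm^-1).
    """

    components: tuple[tuple[str, float], ...]
    baseline: tuple[float, ...] = (0.0,)
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0
    extra_bands: tuple[Band, ...] = ()

    def __post_init__(self) -> None:
        comps = tuple((str(n), float(f)) for n, f in self.components)
        if not comps:
            raise ValueError("a blend needs at least one component")
        for name, frac in comps:
            get_compound(name)  # raises on unknown names
            if frac <= 0:
                raise ValueError(f"weight fraction for {name} must be positive")
        total = sum(f for _, f in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weight fractions sum to {total}, expected 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "baseline", tuple(float(c) for c in self.baseline))


@dataclass
class SynthTruth:
    """Ground truth injected by the generator for one synthetic spectrum."""

    bands: list[Band]
    areas: dict[float, float]  # aggregated areal intensity per band center
    r1: float
    r2: float
    nu_co: float  # area-weighted carbonyl centroid, linked class excluded
    rings_c19: float  # fraction-weighted nominal ring counts
    rings_total: float
    carbonyl_areas: dict[float, float]

    def carbonyl_fraction_below(self, threshold: float) -> float:
        """Fraction of total carbonyl area at centers below ``threshold``."""
        total = sum(self.carbonyl_areas.values())
        if total <= 0:
            return 0.0
        return sum(a for c, a in self.carbonyl_areas.items() if c < threshold) / total


def _truth_bands(spec: BlendSpec) -> tuple[dict[float, float], dict[float, float]]:
    """Aggregate injected band areas by center: (all bands, carbonyl-only)."""
    areas: dict[float, float] = {}
    carbonyl: dict[float, float] = {}

    def add(table: dict[float, float], center: float, area: float) -> None:
        table[center] = table.get(center, 0.0) + area

    for name, frac in spec.components:
        rec = get_compound(name)
        for center, area in AGLYCONE_BAND_AREAS.items():
            add(areas, center, frac * area)
        for center, per_ring in GLUCOSE_BAND_AREAS_PER_RING.items():
            add(areas, center, frac * per_ring * rec.rings_total)
        co_center = CARBONYL_CLASS_CENTERS[rec.rings_c19]
        add(areas, co_center, frac * CARBONYL_BAND_AREA)
        add(carbonyl, co_center, frac * CARBONYL_BAND_AREA)
        if rec.name == "Steviolbioside":
            linked = CARBONYL_CLASS_CENTERS["linked"]
            add(areas, linked, frac * STEVIOLBIOSIDE_LINKED_AREA)
            add(carbonyl, linked, frac * STEVIOLBIOSIDE_LINKED_AREA)
    return areas, carbonyl


def _band_from_area(center: float, area: float,
                    fwhm: float = DEFAULT_FWHM, eta: float = DEFAULT_ETA) -> Band:
    unit = band_area(Band(center=center, fwhm=fwhm, height=1.0, eta=eta))
    return Band(center=center, fwhm=fwhm, height=area / unit, eta=eta)


def synth_spectrum(
    spec: BlendSpec | str,
    axis: tuple[float, float, float] = DEFAULT_AXIS,
) -> tuple[Spectrum, SynthTruth]:
    """Generate a synthetic Raman spectrum and its injected ground truth.

    ``spec`` is either a compound name (pure, noiseless, flat background) or
    a :class:`BlendSpec`.  Deterministic for a given spec: the noise stream
    is seeded from ``spec.seed``.
    """
    if isinstance(spec, str):
        spec = BlendSpec(components=((get_compound(spec).name, 1.0),),
                         noise_sigma=0.0, seed=0)
    lo, hi, step = axis
    nu = np.arange(lo, hi + step / 2, step)

    areas, carbonyl = _truth_bands(spec)
    bands = [_band_from_area(c, a) for c, a in sorted(areas.items())]
    bands += [Band(b.center, b.fwhm, b.height, b.eta) for b in spec.extra_bands]

    y = np.zeros_like(nu)
    for b in bands:
        x = (nu - b.center) / b.fwhm
        y += b.height * (b.eta / (1.0 + 4.0 * x * x)
                         + (1.0 - b.eta) * np.exp(-4.0 * math.log(2.0) * x * x))
    u = (nu - nu[0]) / (nu[-1] - nu[0])
    y += np.polynomial.polynomial.polyval(u, np.asarray(spec.baseline))
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sigma, nu.size)

    co_kept = {c: a for c, a in carbonyl.items() if c < LINKED_CARBONYL_THRESHOLD}
    nu_co = (sum(c * a for c, a in co_kept.items()) / sum(co_kept.values())
             if co_kept else float("nan"))
    w_c19 = sum(f * get_compound(n).rings_c19 for n, f in spec.components)
    w_tot = sum(f * get_compound(n).rings_total for n, f in spec.components)
    truth = SynthTruth(
        bands=bands,
        areas=areas,
        r1=areas[887.0] / areas[898.0],
        r2=(areas[1192.0] + areas[1215.0]) / areas[1204.0],
        nu_co=nu_co,
        rings_c19=w_c19,
        rings_total=w_tot,
        carbonyl_areas=carbonyl,
    )
    meta = {
        "synthetic": True,
        "components": list(spec.components),
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    return Spectrum(nu, y, meta), truth
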