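"""Exact monoisotopic-mass arithmetic for intact proteins.

This module holds the atomic bookkeeping that everything else builds on:
elemental compositions, monoisotopic masses of modified proteoforms,
isotope-envelope computation by convolution, and the proton-adduct charge
algebra used to move between neutral masses and observed m/z values.

All masses are monoisotopic and in daltons.  Average masses are deliberately
not supported: sub-ppm agreement with deconvoluted intact-protein masses is
only possible on the monoisotopic scale.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PROTON_MASS",
    "WATER_MONO",
    "DISULFIDE_DELTA",
    "ElementalComposition",
    "ProteinSpec",
    "ModificationDef",
    "ProteoformComposition",
    "monoisotopic_mass",
    "base_mass",
    "isotope_distribution",
    "deconvolve_charge",
    "charge_mz",
    "default_alphabet",
    "GLYCAN_UNITS",
]

# CODATA/IUPAC monoisotopic atomic masses (lightest stable isotope), Da.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Mass of the proton (positive-mode charge carrier), Da.
PROTON_MASS = 1.007276467

# IUPAC isotopic compositions for the supported elements:
# element -> list of (nominal mass offset from lightest isotope, mass, abundance)
ISOTOPE_TABLE: dict[str, list[tuple[int, float, float]]] = {
    "C": [(0, 12.0, 0.9893), (1, 13.0033548378, 0.0107)],
    "H": [(0, 1.0078250319, 0.999885), (1, 2.0141017780, 0.000115)],
    "N": [(0, 14.0030740052, 0.99636), (1, 15.0001088984, 0.00364)],
    "O": [
        (0, 15.9949146221, 0.99757),
        (1, 16.9991315, 0.00038),
        (2, 17.9991604, 0.00205),
    ],
    "S": [
        (0, 31.97207069, 0.9499),
        (1, 32.97145850, 0.0075),
        (2, 33.96786683, 0.0425),
        (4, 35.96708088, 0.0001),
    ],
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalComposition:
    """Non-negative integer counts per chemical element.

    Compositions form a commutative monoid under ``+``; ``-`` is partial
    (subtracting more atoms than are present raises ``ValueError``).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for el, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
            if int(n) != n:
                raise ValueError(f"non-integer count for element {el!r}: {n}")
            if n:
                clean[el] = int(n)
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        """Parse a Hill-style formula such as ``"C8H13NO5"`` or ``"CO2"``."""
        counts: Counter[str] = Counter()
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            counts[match.group(1)] += int(match.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(dict(counts))

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return ElementalComposition(dict(merged))

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = Counter(self.counts)
        merged.subtract(other.counts)
        if any(v < 0 for v in merged.values()):
            raise ValueError(
                "composition subtraction would yield negative element counts"
            )
        return ElementalComposition({k: v for k, v in merged.items() if v})

    def __mul__(self, n: int) -> "ElementalComposition":
        return ElementalComposition({el: c * n for el, c in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (0 for the empty composition)."""
        try:
            return sum(MONOISOTOPIC_MASS[el] * n for el, n in self.counts.items())
        except KeyError as exc:
            raise KeyError(f"no monoisotopic mass for element {exc.args[0]!r}") from exc

    def __str__(self) -> str:
        order = ["C", "H", "N", "O", "S"]
        keys = [k for k in order if k in self.counts]
        keys += sorted(set(self.counts) - set(order))
        return "".join(f"{k}{self.counts[k] if self.counts[k] != 1 else ''}" for k in keys)


# Residue (i.e. amino acid minus water) elemental compositions, 20 standard letters.
_RESIDUE_FORMULAS = {
    "G": "C2H3NO", "A": "C3H5NO", "S": "C3H5NO2", "P": "C5H7NO",
    "V": "C5H9NO", "T": "C4H7NO2", "C": "C3H5NOS", "L": "C6H11NO",
    "I": "C6H11NO", "N": "C4H6N2O2", "D": "C4H5NO3", "Q": "C5H8N2O2",
    "K": "C6H12N2O", "E": "C5H7NO3", "M": "C5H9NOS", "H": "C6H7N3O",
    "F": "C9H9NO", "R": "C6H12N4O", "Y": "C9H9NO2", "W": "C11H10N2O",
}
RESIDUE_COMPOSITION: dict[str, ElementalComposition] = {
    aa: ElementalComposition.from_formula(f) for aa, f in _RESIDUE_FORMULAS.items()
}

WATER = ElementalComposition.from_formula("H2O")
WATER_MONO = WATER.mass  # 18.0105646...

#: Mass removed per disulfide bond (loss of two hydrogens), Da.
DISULFIDE_DELTA = -2 * MONOISOTOPIC_MASS["H"]  # -2.0156500...

#: Building blocks of the mucin-type core-1 O-glycan and other deltas.
GLYCAN_UNITS: dict[str, ElementalComposition] = {
    "HexNAc": ElementalComposition.from_formula("C8H13NO5"),   # +203.07937
    "Hex": ElementalComposition.from_formula("C6H10O5"),       # +162.05282
    "NeuAc": ElementalComposition.from_formula("C11H17NO8"),   # +291.09542
}


@dataclass(frozen=True)
class ProteinSpec:
    """A mature protein chain with its modifiable-site inventory.

    Positions are 1-based on the mature chain (the numbering used for the
    osteocalcin S8 / Y12 sites).  The intramolecular disulfide is treated as
    formed by default in all theoretical masses.
    """

    id: str
    residues: str
    disulfide_bonds: tuple[tuple[int, int], ...] = ()
    gla_sites: tuple[int, ...] = ()
    glycosites: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.strip().upper())
        object.__setattr__(self, "disulfide_bonds",
                           tuple(tuple(b) for b in self.disulfide_bonds))
        object.__setattr__(self, "gla_sites", tuple(self.gla_sites))
        object.__setattr__(self, "glycosites", tuple(self.glycosites))
        n = len(self.residues)
        for aa in self.residues:
            if aa not in RESIDUE_COMPOSITION:
                raise ValueError(f"unknown residue letter {aa!r} in {self.id}")
        for pair in self.disulfide_bonds:
            for pos in pair:
                self._check_site(pos, n, {"C"}, "disulfide")
        for pos in self.gla_sites:
            self._check_site(pos, n, {"E"}, "gla_site")
        for pos in self.glycosites:
            self._check_site(pos, n, {"S", "T"}, "glycosite")

    def _check_site(self, pos: int, n: int, allowed: set[str], kind: str) -> None:
        if not 1 <= pos <= n:
            raise ValueError(f"{kind} position {pos} outside [1, {n}] in {self.id}")
        aa = self.residues[pos - 1]
        if aa not in allowed:
            raise ValueError(
                f"{kind} position {pos} is {aa!r}, expected one of {sorted(allowed)}"
                f" in {self.id}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_composition(self) -> ElementalComposition:
        """Elemental composition of the unmodified chain (one water, no S-S)."""
        total = WATER
        for aa in self.residues:
            total = total + RESIDUE_COMPOSITION[aa]
        return total


@dataclass(frozen=True)
class ModificationDef:
    """A named mass delta with count bounds and a site-class constraint.

    ``delta`` may be an :class:`ElementalComposition` or a bare mass in Da for
    deltas with no meaningful elemental formula.  ``site_class`` is one of
    ``gla_site``, ``glycosite``, ``any``, ``none``.
    """

    name: str
    delta: ElementalComposition | float
    max_count: int
    site_class: str = "any"

    def __post_init__(self) -> None:
        if self.max_count < 0:
            raise ValueError("max_count must be non-negative")
        if self.site_class not in {"gla_site", "glycosite", "any", "none"}:
            raise ValueError(f"unknown site_class {self.site_class!r}")

    @property
    def mass(self) -> float:
        if isinstance(self.delta, ElementalComposition):
            return self.delta.mass
        return float(self.delta)


@dataclass(frozen=True)
class ProteoformComposition:
    """Modification counts on top of the base proteoform.

    ``counts`` maps modification names (e.g. ``"Gla"``, ``"HexNAc"``) to
    non-negative integers.  ``residual_mass`` carries any leftover mass the
    alphabet could not explain (0 for fully assigned forms).
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    residual_mass: float = 0.0

    def __post_init__(self) -> None:
        clean = {}
        for name, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for modification {name!r}")
            if n:
                clean[name] = int(n)
        object.__setattr__(self, "counts", clean)
        if self.residual_mass < 0:
            raise ValueError("residual_mass must be >= 0")

    def total_count(self) -> int:
        return sum(self.counts.values())

    def get(self, name: str) -> int:
        return self.counts.get(name, 0)

    def delta_mass(self, alphabet: Sequence[ModificationDef]) -> float:
        """Summed delta mass over an alphabet (residual included)."""
        by_name = {m.name: m for m in alphabet}
        total = self.residual_mass
        for name, n in self.counts.items():
            total += by_name[name].mass * n
        return total

    def sort_key(self) -> tuple:
        return tuple(sorted(self.counts.items()))

    def __str__(self) -> str:
        if not self.counts and not self.residual_mass:
            return "unmodified"
        parts = [f"{n}x {name}" if n > 1 else name
                 for name, n in sorted(self.counts.items())]
        if self.residual_mass:
            parts.append(f"+{self.residual_mass:.4f} Da residual")
        return " + ".join(parts)


def default_alphabet(protein: ProteinSpec, *, oxidation_max: int = 2) -> list[ModificationDef]:
    """The standard modification alphabet for a carboxylated, O-glycosylated protein.

    Gla (one CO2 per gamma-carboxyglutamate) is bounded by the number of
    carboxylatable glutamates; the core-1 glycan units are bounded by the
    glycosite inventory (at most one GalNAc per site, one Gal per GalNAc, two
    sialic acids per Gal); oxidation is a small catch-all bound.
    """
    n_sites = len(protein.glycosites)
    return [
        ModificationDef("Gla", ElementalComposition.from_formula("CO2"),
                        max_count=len(protein.gla_sites), site_class="gla_site"),
        ModificationDef("HexNAc", GLYCAN_UNITS["HexNAc"],
                        max_count=n_sites, site_class="glycosite"),
        ModificationDef("Hex", GLYCAN_UNITS["Hex"],
                        max_count=n_sites, site_class="glycosite"),
        ModificationDef("NeuAc", GLYCAN_UNITS["NeuAc"],
                        max_count=2 * n_sites, site_class="glycosite"),
        ModificationDef("Ox", ElementalComposition.from_formula("O"),
                        max_count=oxidation_max, site_class="any"),
    ]


def monoisotopic_mass(
    protein: ProteinSpec,
    composition: ProteoformComposition | None = None,
    alphabet: Sequence[ModificationDef] | None = None,
    *,
    disulfides_formed: bool = True,
) -> float:
    """Neutral monoisotopic mass of a proteoform.

    The mass is the sum of residue masses plus one water, minus two hydrogens
    per formed disulfide bond, plus the summed modification deltas.  Counts
    are checked against the alphabet bounds.
    """
    mass = protein.chain_composition.mass
    if disulfides_formed:
        mass += DISULFIDE_DELTA * len(protein.disulfide_bonds)
    if composition is not None and (composition.counts or composition.residual_mass):
        if alphabet is None:
            alphabet = default_alphabet(protein)
        by_name = {m.name: m for m in alphabet}
        for name, n in composition.counts.items():
            if name not in by_name:
                raise KeyError(f"modification {name!r} not in alphabet")
            if n > by_name[name].max_count:
                raise ValueError(
                    f"{name} count {n} exceeds bound {by_name[name].max_count}"
                )
        mass += composition.delta_mass(alphabet)
    return mass


def base_mass(protein: ProteinSpec) -> float:
    """Uncarboxylated, disulfide-formed mass: the reference all deltas count from."""
    return monoisotopic_mass(protein)


def _convolve(a: dict[int, tuple[float, float]],
              b: dict[int, tuple[float, float]],
              prune: float) -> dict[int, tuple[float, float]]:
    # distributions are {nominal offset: (probability, probability-weighted mass)}
    out: dict[int, list[float]] = {}
    for ka, (pa, ma) in a.items():
        for kb, (pb, mb) in b.items():
            p = pa * pb
            if p <= 0.0:
                continue
            acc = out.setdefault(ka + kb, [0.0, 0.0])
            acc[0] += p
            # centroid masses combine additively, weighted by joint probability
            acc[1] += p * (ma / pa + mb / pb)
    if prune > 0.0:
        out = {k: v for k, v in out.items() if v[0] >= prune}
    return {k: (p, wm) for k, (p, wm) in out.items()}


def isotope_distribution(
    composition: ElementalComposition,
    prune_threshold: float = 1e-6,
) -> list[tuple[int, float, float]]:
    """Aggregated isotope envelope of an elemental composition.

    Returns ``(nominal mass offset, centroid mass, probability)`` triples
    sorted by mass, computed by iterated convolution of the per-element
    isotope distributions (exponentiation by squaring per element).
    Isotopologues are aggregated by nominal offset; the reported mass of each
    peak is the probability-weighted centroid.  With ``prune_threshold=0`` the
    probabilities sum to exactly 1 (up to float rounding).
    """
    if not composition:
        raise ValueError("isotope distribution of the empty composition is undefined")
    if not 0.0 <= prune_threshold < 1.0:
        raise ValueError("prune_threshold must be in [0, 1)")

    dist: dict[int, tuple[float, float]] = {0: (1.0, 0.0)}
    for el, n in composition.counts.items():
        if el not in ISOTOPE_TABLE:
            raise KeyError(f"no isotope table for element {el!r}")
        single = {off: (p, p * m) for off, m, p in ISOTOPE_TABLE[el]}
        # binary exponentiation of the single-atom distribution
        power = single
        k = n
        while k:
            if k & 1:
                dist = _convolve(dist, power, prune_threshold)
            k >>= 1
            if k:
                power = _convolve(power, power, prune_threshold)
    peaks = [(off, wm / p, p) for off, (p, wm) in dist.items() if p > 0.0]
    peaks.sort(key=lambda t: t[1])
    return peaks


def deconvolve_charge(mz: float, z: int) -> float:
    """Neutral monoisotopic mass from an observed m/z at known positive charge z.

    Protonation convention: ``M = z * (m/z) - z * m_proton``.
    """
    if z < 1:
        raise ValueError("charge z must be a positive integer")
    if mz <= PROTON_MASS:
        raise ValueError("m/z must exceed the proton mass")
    return z * mz - z * PROTON_MASS


def charge_mz(neutral_mass: float, z: int) -> float:
    """m/z of the z-fold protonated species; exact inverse of deconvolve_charge."""
    if z < 1:
        raise ValueError("charge z must be a positive integer")
    return (neutral_mass + z * PROTON_MASS) / z
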