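"""Assignment of deconvoluted intact masses to PTM compositions.

Given a list of neutral monoisotopic masses from a deconvoluted top-down
spectrum, each observation is matched against the combinatorial space of
modification compositions of the target protein: gamma-carboxylations (Gla),
core-1 O-glycan units (GalNAc / Gal / sialic acid) and oxidations.  The
search is a bounded depth-first enumeration with branch-and-bound pruning on
the remaining mass, ranked parsimony-first.  Masses that no composition
explains exactly are anchored to the largest composition that fits below
them, with the leftover reported as an unexplained residual — mirroring how
intact-mass tables group adduct ions and unidentified modifications onto a
named proteoform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .masscalc import (
    ModificationDef,
    ProteinSpec,
    ProteoformComposition,
    base_mass,
    default_alphabet,
)

__all__ = [
    "MassObservation",
    "Assignment",
    "enumerate_compositions",
    "rank_candidates",
    "assign_masses",
    "core1_constraint",
    "modification_label",
    "oligosaccharide_label",
]

#: Compositions are reported "exact" when within this many ppm of the
#: observed mass (tolerance measured on the full proteoform mass).  10 ppm
#: admits the spread seen among published intact-OCN mass tables while the
#: instrument-level accuracy is ~5 ppm.
DEFAULT_TOLERANCE_PPM = 10.0

#: Unexplained-mass window for residual-anchored assignments, Da.  Published
#: intact-mass ledgers group up to ~235 Da of adducts onto one anchor form.
DEFAULT_RESIDUAL_WINDOW = 250.0


@dataclass(frozen=True)
class MassObservation:
    """One deconvoluted neutral monoisotopic mass with optional abundance."""

    neutral_mass: float
    relative_abundance: float | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be positive")
        if self.relative_abundance is not None and not 0 <= self.relative_abundance <= 100:
            raise ValueError("relative_abundance must be within [0, 100]")


@dataclass(frozen=True)
class Assignment:
    """Ranked candidate compositions for one observation.

    ``status`` is ``exact`` (an in-tolerance composition exists), ``residual``
    (anchored to a composition plus unexplained leftover mass) or
    ``unassigned``.  ``negative_delta`` flags observations below the base
    proteoform mass beyond tolerance.
    """

    observation: MassObservation
    candidates: tuple[tuple[ProteoformComposition, float], ...]
    status: str
    negative_delta: bool = False

    @property
    def best(self) -> ProteoformComposition | None:
        return self.candidates[0][0] if self.candidates else None

    @property
    def best_ppm(self) -> float | None:
        return self.candidates[0][1] if self.candidates else None


def core1_constraint(max_sites: int) -> Callable[[dict[str, int]], bool]:
    """Mucin-type core-1 admissibility test on aggregate glycan-unit counts.

    A composition is admissible when its units can be laid out on at most
    ``max_sites`` glycosites as GalNAc(-Gal(-NeuAc 0..2)) chains: one GalNAc
    per occupied site, at most one Gal per GalNAc, at most two sialic acids
    per Gal.
    """

    def ok(counts: dict[str, int]) -> bool:
        hexnac = counts.get("HexNAc", 0)
        hexose = counts.get("Hex", 0)
        neuac = counts.get("NeuAc", 0)
        return hexnac <= max_sites and hexose <= hexnac and neuac <= 2 * hexose

    return ok


def enumerate_compositions(
    target_delta: float,
    alphabet: Sequence[ModificationDef],
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    reference_mass: float | None = None,
    constraint: Callable[[dict[str, int]], bool] | None = None,
) -> list[ProteoformComposition]:
    """All modification compositions whose summed delta matches ``target_delta``.

    The tolerance is expressed in ppm of ``reference_mass`` — the full
    proteoform mass, not the delta — since that is the scale on which the
    instrument error lives.  Implemented as depth-first enumeration over
    count vectors with pruning on the attainable mass range of the remaining
    alphabet.
    """
    if not alphabet:
        raise ValueError("modification alphabet is empty")
    if reference_mass is None:
        reference_mass = abs(target_delta)
    tol_da = tolerance_ppm * 1e-6 * reference_mass

    mods = list(alphabet)
    # suffix sums of the maximal attainable mass, for branch pruning
    max_tail = [0.0] * (len(mods) + 1)
    for i in range(len(mods) - 1, -1, -1):
        max_tail[i] = max_tail[i + 1] + max(mods[i].mass, 0.0) * mods[i].max_count
    min_tail = [0.0] * (len(mods) + 1)
    for i in range(len(mods) - 1, -1, -1):
        min_tail[i] = min_tail[i + 1] + min(mods[i].mass, 0.0) * mods[i].max_count

    results: list[ProteoformComposition] = []
    counts: dict[str, int] = {}

    def recurse(i: int, acc: float) -> None:
        remaining = target_delta - acc
        if remaining - max_tail[i] > tol_da or remaining - min_tail[i] < -tol_da:
            return
        if i == len(mods):
            if abs(remaining) <= tol_da:
                if constraint is None or constraint(counts):
                    results.append(ProteoformComposition(dict(counts)))
            return
        mod = mods[i]
        for n in range(mod.max_count + 1):
            if n:
                counts[mod.name] = n
            recurse(i + 1, acc + mod.mass * n)
        counts.pop(mod.name, None)

    recurse(0, 0.0)
    return results


def rank_candidates(
    candidates: Sequence[ProteoformComposition],
    ppm_errors: Sequence[float],
) -> list[tuple[ProteoformComposition, float]]:
    """Parsimony-first ranking of candidate compositions.

    Sort key: fewest total modification count, then smallest absolute ppm
    error, then lexicographic composition order (a deterministic last resort).
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    paired = list(zip(candidates, ppm_errors))
    paired.sort(key=lambda ce: (ce[0].total_count(), abs(ce[1]), ce[0].sort_key()))
    return paired


def _enumerate_below(
    limit: float,
    alphabet: Sequence[ModificationDef],
    constraint: Callable[[dict[str, int]], bool] | None,
) -> Iterable[tuple[dict[str, int], float]]:
    """All compositions with summed mass <= limit (all deltas assumed >= 0)."""
    mods = list(alphabet)
    counts: dict[str, int] = {}

    def recurse(i: int, acc: float):
        if i == len(mods):
            if constraint is None or constraint(counts):
                yield dict(counts), acc
            return
        mod = mods[i]
        for n in range(mod.max_count + 1):
            total = acc + mod.mass * n
            if total > limit:
                break
            if n:
                counts[mod.name] = n
            yield from recurse(i + 1, total)
        counts.pop(mod.name, None)

    yield from recurse(0, 0.0)


def assign_masses(
    observations: Sequence[MassObservation],
    protein: ProteinSpec,
    alphabet: Sequence[ModificationDef] | None = None,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    residual_window: float = DEFAULT_RESIDUAL_WINDOW,
    *,
    enforce_core1: bool = True,
) -> list[Assignment]:
    """Assign each observed neutral mass to ranked PTM compositions.

    Deltas are measured from the uncarboxylated, disulfide-formed base mass;
    Gla is an ordinary alphabet member, so "glycan only" means zero Gla.  For
    each observation the status is ``exact`` when an in-tolerance composition
    exists, else ``residual`` when some composition sits within
    ``residual_window`` Da below the observation (the largest such
    composition is the anchor and the leftover is reported as residual mass),
    else ``unassigned``.
    """
    if alphabet is None:
        alphabet = default_alphabet(protein)
    constraint = core1_constraint(len(protein.glycosites)) if enforce_core1 else None
    base = base_mass(protein)

    out: list[Assignment] = []
    for obs in observations:
        delta = obs.neutral_mass - base
        tol_da = tolerance_ppm * 1e-6 * obs.neutral_mass
        exact = enumerate_compositions(
            delta, alphabet, tolerance_ppm, obs.neutral_mass, constraint
        )
        if exact:
            ppm = [
                (delta - c.delta_mass(alphabet)) / obs.neutral_mass * 1e6
                for c in exact
            ]
            out.append(Assignment(obs, tuple(rank_candidates(exact, ppm)), "exact"))
            continue
        if delta < -tol_da:
            out.append(Assignment(obs, (), "unassigned", negative_delta=True))
            continue
        # residual: anchor on the largest composition fitting under the mass
        best: tuple[float, tuple, dict[str, int]] | None = None
        for counts, mass in _enumerate_below(delta + tol_da, alphabet, constraint):
            leftover = delta - mass
            if leftover > residual_window:
                continue
            key = (mass, tuple(sorted(counts.items())))
            if best is None or key > best[:2]:
                best = (mass, key[1], counts)
        if best is not None:
            anchor = ProteoformComposition(best[2], residual_mass=max(delta - best[0], 0.0))
            ppm_err = (delta - best[0] - anchor.residual_mass) / obs.neutral_mass * 1e6
            out.append(Assignment(obs, ((anchor, ppm_err),), "residual"))
        else:
            out.append(Assignment(obs, (), "unassigned"))
    return out


_GLYCAN_NAMES = ("HexNAc", "Hex", "NeuAc")


def oligosaccharide_label(comp: ProteoformComposition) -> str:
    """Oligosaccharide summary in the conventional notation, e.g. ``"HexNAc, Hex, 2x NANA"``."""
    parts = []
    display = {"HexNAc": "HexNAc", "Hex": "Hex", "NeuAc": "NANA"}
    for unit in _GLYCAN_NAMES:
        n = comp.get(unit)
        if n == 1:
            parts.append(display[unit])
        elif n > 1:
            parts.append(f"{n}x {display[unit]}")
    return ", ".join(parts) if parts else "NA"


def modification_label(comp: ProteoformComposition) -> str:
    """Modification summary in the conventional ledger notation.

    Glycan units are folded into a single "Glycosylation" word (doubled when
    two glycan chains are present); Gla and oxidation counts are spelled out;
    a nonzero residual appears as "additional unidentified modifications or
    adduct ions".
    """
    parts: list[str] = []
    n_chains = comp.get("HexNAc")
    if n_chains == 1:
        parts.append("Glycosylation")
    elif n_chains > 1:
        parts.append(f"{n_chains}x Glycosylation")
    n_gla = comp.get("Gla")
    if n_gla:
        parts.append(f"{n_gla}x Gla")
    n_ox = comp.get("Ox")
    if n_ox == 1:
        parts.append("oxidation")
    elif n_ox > 1:
        parts.append(f"{n_ox}x oxidation")
    if comp.residual_mass > 0:
        parts.append("additional unidentified modifications or adduct ions")
    if not parts:
        return "unmodified"
    return " + ".join(parts)
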