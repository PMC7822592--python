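"""Proteoform-class ledgers: classify assignments and aggregate abundances.

Turns a list of per-mass assignments into the class-level summaries used in
intact-mass studies: glycosylated vs non-glycosylated totals, breakdown by
oligosaccharide, by carboxylation (Gla) count, or by the number of glycan
chains, plus the purified-protein glycosylated / two-adduct fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .assignment import Assignment, oligosaccharide_label

__all__ = ["AbundanceTable", "classify", "aggregate", "glyco_fraction"]

GROUPINGS = ("glyco_vs_not", "by_oligosaccharide", "by_gla_count", "by_glycan_multiplicity")


@dataclass(frozen=True)
class AbundanceTable:
    """Per-class relative abundances (percent), sorted descending."""

    rows: pd.DataFrame  # columns: class_label, relative_abundance
    grouping: str

    def total(self) -> float:
        return float(self.rows["relative_abundance"].sum())

    def get(self, class_label: str) -> float:
        hit = self.rows.loc[self.rows["class_label"] == class_label, "relative_abundance"]
        return float(hit.iloc[0]) if len(hit) else 0.0


def classify(assignment: Assignment, grouping: str = "glyco_vs_not") -> str:
    """Class label of an assignment's rank-1 candidate under a grouping.

    A proteoform counts as glycosylated iff its leading candidate carries at
    least one HexNAc (the initiating GalNAc of a mucin-type O-glycan).
    Unassigned observations are routed to the class ``"unassigned"``.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    best = assignment.best
    if best is None:
        return "unassigned"
    if grouping == "glyco_vs_not":
        return "glycosylated" if best.get("HexNAc") >= 1 else "non-glycosylated"
    if grouping == "by_oligosaccharide":
        return oligosaccharide_label(best)
    if grouping == "by_gla_count":
        return f"{best.get('Gla')}x Gla"
    return f"{best.get('HexNAc')} glycan(s)"  # by_glycan_multiplicity


def aggregate(
    assignments: list[Assignment],
    grouping: str = "glyco_vs_not",
    *,
    include_unassigned: bool = True,
) -> AbundanceTable:
    """Sum observation abundances into class totals.

    Conservation holds exactly: the class totals sum to the input total.  By
    default unassigned observations stay in the denominator as their own
    class; ``include_unassigned=False`` drops them.
    """
    missing = [a.observation.source_label or f"{a.observation.neutral_mass:.4f}"
               for a in assignments if a.observation.relative_abundance is None]
    if missing:
        raise ValueError(f"observations missing relative abundance: {missing}")
    rows = [
        (classify(a, grouping), a.observation.relative_abundance)
        for a in assignments
    ]
    if not include_unassigned:
        rows = [r for r in rows if r[0] != "unassigned"]
    frame = pd.DataFrame(rows, columns=["class_label", "relative_abundance"])
    table = (
        frame.groupby("class_label", as_index=False)["relative_abundance"]
        .sum()
        .sort_values("relative_abundance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return AbundanceTable(table, grouping)


def glyco_fraction(assignments: list[Assignment]) -> tuple[float, float]:
    """Intensity-weighted glycosylated fraction and two-adduct fraction.

    Returns ``(fraction_glycosylated, fraction_two_adducts)`` where the
    second is conditional on the glycosylated pool (the share of glycosylated
    signal carrying two or more glycan chains).  For an all-unglycosylated
    input the conditional fraction is undefined and reported as 0.
    """
    weights = [a.observation.relative_abundance for a in assignments]
    if any(w is None for w in weights):
        raise ValueError("all observations need an abundance/intensity")
    total = float(sum(weights))
    if total <= 0:
        raise ValueError("zero total intensity")
    glyco = sum(
        w for a, w in zip(assignments, weights)
        if a.best is not None and a.best.get("HexNAc") >= 1
    )
    multi = sum(
        w for a, w in zip(assignments, weights)
        if a.best is not None and a.best.get("HexNAc") >= 2
    )
    frac_glyco = glyco / total
    frac_two = (multi / glyco) if glyco > 0 else 0.0
    return frac_glyco, frac_two
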