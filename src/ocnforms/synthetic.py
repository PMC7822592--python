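"""Synthetic data with the statistical structure the pipeline assumes.

Generates the two kinds of input the analysis consumes:

* deconvoluted intact-mass lists (and rendered isotope-envelope spectra)
  drawn from a known proteoform mixture, with ppm-scale Gaussian mass error
  and lognormal intensity noise — the structure of a deconvoluted top-down
  run on a mixture of modified forms of one protein;

* mono-exponential concentration time courses with replicate-level
  multiplicative (lognormal) measurement noise, for both the ex vivo design
  (decay from t = 0) and the in vivo design (linear rise to a peak, then
  first-order decline) — the structure of ELISA-read stability assays.

All generators take an explicit integer seed and are bit-reproducible; no
global random state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import DecayCurve
from .masscalc import (
    ModificationDef,
    ProteinSpec,
    ProteoformComposition,
    charge_mz,
    default_alphabet,
    isotope_distribution,
    monoisotopic_mass,
    ElementalComposition,
    GLYCAN_UNITS,
)
from .assignment import MassObservation

__all__ = ["MixtureTruth", "DecayTruth", "simulate_mass_list",
           "simulate_spectrum", "simulate_decay"]


@dataclass(frozen=True)
class MixtureTruth:
    """Ground-truth proteoform mixture for the mass-list generator."""

    components: tuple[tuple[ProteoformComposition, float], ...]
    ppm_noise_sd: float = 0.0
    abundance_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        weights = [w for _, w in self.components]
        if not weights or not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
            raise ValueError("component weights must sum to 1")
        if self.ppm_noise_sd < 0 or self.abundance_noise_cv < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class DecayTruth:
    """Ground-truth decay design: half-life, sampling grid, replication, noise."""

    t_half: float  # minutes; math.inf for a stable analyte
    c0: float = 100.0  # ng/ml (peak concentration for the in vivo design)
    sample_times: tuple[float, ...] = (0, 60, 120, 180, 240, 300)
    n_replicates: int = 4
    noise_cv: float = 0.05
    peak_time: float = 0.0  # 0 = ex vivo decay from baseline
    seed: int = 0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sample_times)
        if list(times) != sorted(times):
            raise ValueError("sample_times must be sorted")
        object.__setattr__(self, "sample_times", times)
        if self.t_half <= 0:
            raise ValueError("t_half must be positive (use inf for stable)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


def simulate_mass_list(
    truth: MixtureTruth,
    protein: ProteinSpec,
    alphabet: Sequence[ModificationDef] | None = None,
) -> list[MassObservation]:
    """Draw a deconvoluted mass list from a known proteoform mixture.

    Each component's observed mass is its theoretical monoisotopic mass times
    ``(1 + eps)`` with ``eps ~ Normal(0, ppm_noise_sd * 1e-6)``; abundances
    are the mixture weights perturbed by lognormal noise at the stated CV and
    renormalised to 100 %.
    """
    if alphabet is None:
        alphabet = default_alphabet(protein)
    rng = np.random.default_rng(truth.seed)
    n = len(truth.components)
    eps = rng.normal(0.0, truth.ppm_noise_sd * 1e-6, size=n)
    raw = np.array([w for _, w in truth.components]) * _lognormal_factors(
        rng, truth.abundance_noise_cv, n
    )
    abundances = raw / raw.sum() * 100.0
    out = []
    for i, (comp, _) in enumerate(truth.components):
        theo = monoisotopic_mass(protein, comp, alphabet)
        out.append(
            MassObservation(
                neutral_mass=theo * (1.0 + eps[i]),
                relative_abundance=float(abundances[i]),
                source_label=f"sim_{i}:{comp}",
            )
        )
    return out


def simulate_spectrum(
    truth: MixtureTruth,
    protein: ProteinSpec,
    charges: Sequence[int] = (4, 5, 6),
    resolution_fwhm: float = 70000.0,
    alphabet: Sequence[ModificationDef] | None = None,
    mz_range: tuple[float, float] = (600.0, 2000.0),
    points_per_fwhm: float = 6.0,
    prune_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Render the mixture as a profile-mode m/z spectrum.

    Each component contributes its isotope envelope (residual mass, when
    present, is treated as a rigid shift) at each charge state, with Gaussian
    peak shapes whose FWHM follows the stated resolving power (FWHM =
    mz / resolution).  Returns a DataFrame with columns ``mz``, ``intensity``.
    """
    if any(z < 1 for z in charges):
        raise ValueError("charges must be positive")
    if alphabet is None:
        alphabet = default_alphabet(protein)
    by_name = {m.name: m for m in alphabet}

    lo, hi = mz_range
    step = (lo / resolution_fwhm) / points_per_fwhm
    grid = np.arange(lo, hi, step)
    intensity = np.zeros_like(grid)

    for comp, weight in truth.components:
        elemental = protein.chain_composition
        shift = comp.residual_mass
        # two hydrogens leave per disulfide: subtract from the formula
        elemental = elemental - ElementalComposition(
            {"H": 2 * len(protein.disulfide_bonds)}
        )
        for name, n in comp.counts.items():
            delta = by_name[name].delta
            if isinstance(delta, ElementalComposition):
                elemental = elemental + n * delta
            else:
                shift += n * float(delta)
        envelope = isotope_distribution(elemental, prune_threshold)
        for z in charges:
            for _, mass, prob in envelope:
                center = charge_mz(mass + shift, z)
                if not lo <= center <= hi:
                    continue
                fwhm = center / resolution_fwhm
                sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
                window = (grid > center - 5 * sigma) & (grid < center + 5 * sigma)
                intensity[window] += (
                    weight * prob
                    * np.exp(-0.5 * ((grid[window] - center) / sigma) ** 2)
                )
    return pd.DataFrame({"mz": grid, "intensity": intensity})


def simulate_decay(truth: DecayTruth) -> DecayCurve:
    """Simulate a concentration time course under the stated decay truth.

    Ex vivo (``peak_time == 0``): ``C(t) = c0 * 2**(-t / t_half)``.  In vivo
    (``peak_time > 0``): linear rise from 0 to ``c0`` at the peak, then the
    same first-order decline measured from the peak.  Every record gets
    independent multiplicative lognormal noise at ``noise_cv``.
    """
    rng = np.random.default_rng(truth.seed)
    times = np.array(truth.sample_times)

    def clean(t: np.ndarray) -> np.ndarray:
        if truth.peak_time > 0:
            rising = np.minimum(t, truth.peak_time) / truth.peak_time * truth.c0
            decline_t = np.maximum(t - truth.peak_time, 0.0)
        else:
            rising = np.full_like(t, truth.c0, dtype=float)
            decline_t = t
        if math.isinf(truth.t_half):
            decay = np.ones_like(t, dtype=float)
        else:
            decay = 2.0 ** (-decline_t / truth.t_half)
        return np.where(t < truth.peak_time, rising, truth.c0 * decay)

    frames = []
    expected = clean(times)
    for r in range(truth.n_replicates):
        noise = _lognormal_factors(rng, truth.noise_cv, len(times))
        frames.append(pd.DataFrame({
            "time_min": times,
            "conc_ng_ml": expected * noise,
            "replicate_id": f"rep{r + 1}",
        }))
    baseline = truth.peak_time if truth.peak_time > 0 else 0.0
    return DecayCurve(pd.concat(frames, ignore_index=True), baseline_time=baseline)
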