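"""Composition enumeration, ranking, and mass assignment."""

import itertools

import numpy as np
import pytest

from ocnforms.assignment import (
    MassObservation,
    assign_masses,
    core1_constraint,
    enumerate_compositions,
    rank_candidates,
)
from ocnforms.masscalc import (
    ElementalComposition,
    ModificationDef,
    ProteoformComposition,
    base_mass,
    default_alphabet,
)

# unconstrained example alphabet: Gla<=3, HexNAc<=2, Hex<=2, NeuAc<=4, Ox<=2
EXAMPLE_ALPHABET = [
    ModificationDef("Gla", ElementalComposition.from_formula("CO2"), 3),
    ModificationDef("HexNAc", ElementalComposition.from_formula("C8H13NO5"), 2),
    ModificationDef("Hex", ElementalComposition.from_formula("C6H10O5"), 2),
    ModificationDef("NeuAc", ElementalComposition.from_formula("C11H17NO8"), 4),
    ModificationDef("Ox", ElementalComposition.from_formula("O"), 2),
]


def brute_force(target, alphabet, tol_da, constraint=None):
    """Exhaustive Cartesian-product oracle for composition enumeration."""
    hits = set()
    ranges = [range(m.max_count + 1) for m in alphabet]
    for counts in itertools.product(*ranges):
        mass = sum(n * m.mass for n, m in zip(counts, alphabet))
        named = {m.name: n for m, n in zip(alphabet, counts) if n}
        if abs(mass - target) <= tol_da and (constraint is None or constraint(named)):
            hits.add(tuple(sorted(named.items())))
    return hits


class TestEnumerate:
    @pytest.mark.parametrize(
        "target, expected_best",
        [
            # mono- and di-sialylated core-1 glycan deltas; a second, heavier
            # composition (2x HexNAc + Hex + Gla's) also falls inside 10 ppm at
            # this reference mass, so parsimony ranking must pick the glycan
            (656.2276, {"HexNAc": 1, "Hex": 1, "NeuAc": 1}),
            (947.3230, {"HexNAc": 1, "Hex": 1, "NeuAc": 2}),
        ],
    )
    def test_sialylated_glycan_deltas(self, target, expected_best):
        tol_da = 10e-6 * 5767.7
        got = enumerate_compositions(target, EXAMPLE_ALPHABET, 10.0, 5767.7)
        got_set = {tuple(sorted(c.counts.items())) for c in got}
        assert got_set == brute_force(target, EXAMPLE_ALPHABET, tol_da)
        assert tuple(sorted(expected_best.items())) in got_set
        by_name = {m.name: m for m in EXAMPLE_ALPHABET}
        ppms = [
            (target - sum(by_name[k].mass * v for k, v in c.counts.items()))
            / 5767.7 * 1e6
            for c in got
        ]
        assert rank_candidates(got, ppms)[0][0].counts == expected_best

    def test_zero_target_gives_empty_composition(self):
        got = enumerate_compositions(0.0, EXAMPLE_ALPHABET, 10.0, 5767.7)
        assert [c.counts for c in got] == [{}]

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            enumerate_compositions(100.0, [], 10.0, 5000.0)

    def test_matches_brute_force_oracle_on_random_targets(self):
        """DFS-with-pruning enumeration is exactly the exhaustive product."""
        alphabet = [
            ModificationDef(m.name, m.delta, min(m.max_count, 4))
            for m in EXAMPLE_ALPHABET
        ]
        rng = np.random.default_rng(20240601)
        ref = 5767.7
        tol_da = 10.0 * 1e-6 * ref
        for _ in range(120):
            # half the targets near a real composition mass, half uniform
            if rng.random() < 0.5:
                counts = [rng.integers(0, m.max_count + 1) for m in alphabet]
                target = sum(n * m.mass for n, m in zip(counts, alphabet))
                target += rng.normal(0.0, tol_da)
            else:
                target = rng.uniform(0.0, 1500.0)
            got = {
                tuple(sorted(c.counts.items()))
                for c in enumerate_compositions(target, alphabet, 10.0, ref)
            }
            assert got == brute_force(target, alphabet, tol_da)

    def test_core1_constraint_respected(self):
        """With the core-1 rule, sialic acid requires galactose requires GalNAc."""
        alphabet = EXAMPLE_ALPHABET
        constraint = core1_constraint(max_sites=1)
        tol_da = 10e-6 * 5767.7
        got = {
            tuple(sorted(c.counts.items()))
            for c in enumerate_compositions(453.148, alphabet, 10.0, 5767.7, constraint)
        }
        unconstrained = brute_force(453.148, alphabet, tol_da)
        # NeuAc+Hex without the initiating GalNAc is inadmissible under core-1
        assert (("Hex", 1), ("NeuAc", 1)) in unconstrained
        assert (("Hex", 1), ("NeuAc", 1)) not in got
        assert got == brute_force(453.148, alphabet, tol_da, constraint)

    def test_tolerance_monotonicity(self):
        sets = []
        for tol in (1.0, 5.0, 10.0, 50.0):
            got = {
                tuple(sorted(c.counts.items()))
                for c in enumerate_compositions(947.30, EXAMPLE_ALPHABET, tol, 5767.7)
            }
            sets.append(got)
        for narrow, wide in zip(sets, sets[1:]):
            assert narrow <= wide


class TestRanking:
    def test_parsimony_beats_ppm(self):
        small = ProteoformComposition({"Gla": 3})
        big = ProteoformComposition({"Gla": 2, "Ox": 2, "Hex": 1})
        ranked = rank_candidates([big, small], [0.1, 4.8])
        assert ranked[0][0] is small

    def test_ppm_breaks_count_ties(self):
        a = ProteoformComposition({"Gla": 1})
        b = ProteoformComposition({"Ox": 1})
        ranked = rank_candidates([b, a], [4.8, 1.2])
        assert ranked[0][0] is a

    def test_full_tie_is_lexicographic_and_deterministic(self):
        a = ProteoformComposition({"Gla": 1})
        b = ProteoformComposition({"Ox": 1})
        first = rank_candidates([b, a], [2.0, 2.0])
        second = rank_candidates([a, b], [2.0, 2.0])
        assert [c.counts for c, _ in first] == [c.counts for c, _ in second]
        assert first[0][0].counts == {"Gla": 1}

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates([], [])


class TestAssign:
    def test_mono_sialylated_uncarboxylated_glycoform(self, mouse):
        [a] = assign_masses([MassObservation(5767.6961)], mouse)
        assert a.status == "exact"
        assert a.best.counts == {"HexNAc": 1, "Hex": 1, "NeuAc": 1}

    def test_di_sialylated_two_gla_glycoform(self, mouse):
        [a] = assign_masses([MassObservation(6146.7609)], mouse)
        assert a.status == "exact"
        assert a.best.counts == {"HexNAc": 1, "Hex": 1, "NeuAc": 2, "Gla": 2}

    def test_base_mass_assigns_to_empty_composition(self, mouse):
        [a] = assign_masses([MassObservation(base_mass(mouse))], mouse)
        assert a.status == "exact"
        assert a.best.counts == {}
        assert a.best_ppm == pytest.approx(0.0, abs=1e-9)

    def test_unexplained_mass_gets_residual_anchor(self, mouse):
        """A ledger-range endpoint with no exact composition anchors with leftover mass."""
        [a] = assign_masses([MassObservation(5968.5796)], mouse)
        assert a.status == "residual"
        assert a.best.residual_mass > 0
        assert a.best.get("HexNAc") >= 1  # the anchor is still a glycoform

    def test_mass_below_base_is_unassigned_with_flag(self, mouse):
        [a] = assign_masses([MassObservation(4000.0)], mouse)
        assert a.status == "unassigned"
        assert a.negative_delta
        assert a.candidates == ()

    def test_residual_window_monotonicity(self, mouse):
        obs = [MassObservation(m) for m in (5968.5796, 6300.0, 6441.7636)]
        def residual_set(window):
            assigned = assign_masses(obs, mouse, residual_window=window)
            return {a.observation.neutral_mass for a in assigned if a.status == "residual"}
        narrow, wide = residual_set(50.0), residual_set(250.0)
        assert narrow <= wide

    def test_zero_noise_recovery_of_known_mixture(self, mouse):
        """Masses generated from known compositions come back exact at rank 1."""
        alphabet = default_alphabet(mouse)
        by_name = {m.name: m for m in alphabet}
        truths = [
            {"HexNAc": 1, "Hex": 1, "NeuAc": 1},
            {"HexNAc": 1, "Hex": 1, "NeuAc": 2, "Gla": 2},
            {"HexNAc": 2, "Hex": 2, "NeuAc": 2},
            {"Gla": 3, "Ox": 1},
            {},
        ]
        base = base_mass(mouse)
        obs = [
            MassObservation(base + sum(by_name[k].mass * v for k, v in t.items()))
            for t in truths
        ]
        for a, truth in zip(assign_masses(obs, mouse), truths):
            assert a.status == "exact"
            assert a.best.counts == {k: v for k, v in truth.items() if v}
            assert a.best_ppm == pytest.approx(0.0, abs=1e-6)

    def test_ppm_noise_degrades_recovery_monotonically(self, mouse):
        """Recovery is perfect at 0 ppm noise and does not improve as noise grows."""
        from ocnforms.synthetic import MixtureTruth, simulate_mass_list

        components = (
            (ProteoformComposition({"HexNAc": 1, "Hex": 1, "NeuAc": 1}), 0.4),
            (ProteoformComposition({"HexNAc": 1, "Hex": 1, "NeuAc": 2, "Gla": 2}), 0.4),
            (ProteoformComposition({"Gla": 3, "Ox": 1}), 0.2),
        )
        rates = []
        for ppm_sd in (0.0, 2.0, 5.0, 10.0):
            hits = trials = 0
            for seed in range(30):
                truth = MixtureTruth(components, ppm_noise_sd=ppm_sd, seed=seed)
                obs = simulate_mass_list(truth, mouse)
                for a, (comp, _) in zip(assign_masses(obs, mouse), components):
                    trials += 1
                    hits += a.status == "exact" and a.best.counts == comp.counts
            rates.append(hits / trials)
        assert rates[0] == 1.0
        assert rates[-1] <= rates[0]
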