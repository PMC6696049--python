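"""Pair potential and hydrogen-bond graph behaviour."""

import numpy as np
import pytest

from conftest import random_water
from oracles import (
    exhaustive_energy_only_edges,
    exhaustive_hbond_edges,
    reference_pair_energy,
)
from twnkit.energetics import (
    PotentialParams,
    hbond_graph,
    is_hbonded,
    pair_energies,
    pair_energy,
)
from twnkit.errors import OverlapError
from twnkit.fixtures import ideal_dimer, make_box
from twnkit.io import Frame, WaterMolecule

#: energy of the canonical linear H-bond dimer at O-O = 2.8 A, frozen from
#: an independent term-by-term 9-pair summation
GOLDEN_DIMER_KCAL = -6.1749390609


def _dimer_frame(waters, box=None):
    return Frame(
        index=0,
        o=np.array([w.o_pos for w in waters]),
        h1=np.array([w.h1_pos for w in waters]),
        h2=np.array([w.h2_pos for w in waters]),
        box=box,
    )


class TestPairEnergy:
    def test_golden_linear_dimer(self, params):
        d, a = ideal_dimer(2.8)
        e = pair_energy(d, a, params)
        assert e == pytest.approx(GOLDEN_DIMER_KCAL, abs=1e-8)
        assert e < params.hbond_threshold

    def test_matches_reference_summation_on_random_dimers(self, params, rng):
        for _ in range(300):
            a = random_water(rng, rng.uniform(-5, 5, 3))
            b = random_water(rng, a.o_pos + rng.uniform(2.5, 8.0) * _unit(rng))
            assert pair_energy(a, b, params) == pytest.approx(
                reference_pair_energy(a, b), abs=1e-8
            )

    def test_symmetric_under_pair_swap(self, params, rng):
        for _ in range(100):
            a = random_water(rng, rng.uniform(-3, 3, 3))
            b = random_water(rng, a.o_pos + rng.uniform(2.5, 6.0) * _unit(rng))
            assert pair_energy(a, b, params) == pytest.approx(
                pair_energy(b, a, params), abs=1e-10
            )

    def test_rigid_motion_invariance(self, params, rng):
        from twnkit.fixtures import _random_rotation

        a = random_water(rng, [0.0, 0.0, 0.0])
        b = random_water(rng, [2.9, 0.4, -0.3])
        e0 = pair_energy(a, b, params)
        rot = _random_rotation(rng)
        t = rng.uniform(-20, 20, 3)

        def move(w):
            s = w.sites @ rot.T + t
            return WaterMolecule(s[0], s[1], s[2])

        assert pair_energy(move(a), move(b), params) == pytest.approx(e0, abs=1e-8)

    def test_far_pair_is_weak(self, params, rng):
        for _ in range(10):
            a = random_water(rng, [0.0, 0.0, 0.0])
            b = random_water(rng, 30.0 * _unit(rng))
            assert abs(pair_energy(a, b, params)) < 0.2

    def test_monotone_beyond_minimum_for_fixed_orientation(self, params):
        energies = [pair_energy(*ideal_dimer(oo), params)
                    for oo in np.arange(2.8, 8.0, 0.1)]
        diffs = np.diff(energies)
        assert np.all(diffs >= -1e-12)

    def test_overlapping_molecules_raise(self, params):
        d, a = ideal_dimer(2.8)
        clash = WaterMolecule(d.o_pos + [0.05, 0, 0], a.h1_pos, a.h2_pos)
        with pytest.raises(OverlapError):
            pair_energy(d, clash, params)

    def test_minimum_image_across_boundary(self, params):
        d, a = ideal_dimer(2.8)
        box = np.array([20.0, 20.0, 20.0])
        shifted = WaterMolecule(a.o_pos + box, a.h1_pos + box, a.h2_pos + box)
        assert pair_energy(d, shifted, params, box=box) == pytest.approx(
            pair_energy(d, a, params), abs=1e-8
        )
        assert pair_energy(d, shifted, params, box=box) == pytest.approx(
            reference_pair_energy(d, shifted, box=list(box)), abs=1e-8
        )


class TestHBondClassification:
    def test_threshold_is_inclusive(self, params):
        # scan O-O until the energy crosses the threshold and check the
        # boundary convention on an exactly-at-threshold synthetic value
        d, a = ideal_dimer(2.8)
        assert is_hbonded(d, a, params)
        far_d, far_a = ideal_dimer(6.0)
        assert not is_hbonded(far_d, far_a, params)
        exact = PotentialParams(hbond_threshold=pair_energy(d, a, params))
        assert is_hbonded(d, a, exact)  # energy == threshold => bonded

    def test_vectorized_matches_scalar(self, params, rng):
        frame = make_box(40, 12.0, seed=7)
        pairs = np.array([(i, j) for i in range(40) for j in range(i + 1, 40)])
        vec = pair_energies(frame, pairs, params)
        for k in rng.choice(len(pairs), size=60, replace=False):
            i, j = pairs[k]
            assert vec[k] == pytest.approx(
                pair_energy(frame.water(i), frame.water(j), params,
                            box=frame.box),
                abs=1e-10,
            )


class TestHBondGraph:
    def test_planted_pair_plus_distant_water(self, params):
        d, a = ideal_dimer(2.8)
        far = random_water(np.random.default_rng(0), [20.0, 0.0, 0.0])
        frame = _dimer_frame([d, a, far])
        g = hbond_graph(frame, params)
        assert set(g.nodes) == {0, 1, 2}
        assert set(map(tuple, map(sorted, g.edges))) == {(0, 1)}

    def test_empty_frame_gives_empty_graph(self, params):
        frame = Frame(index=0, o=np.empty((0, 3)), h1=np.empty((0, 3)),
                      h2=np.empty((0, 3)))
        g = hbond_graph(frame, params)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_no_close_pairs_gives_edgeless_graph(self, params):
        rng = np.random.default_rng(1)
        waters = [random_water(rng, [8.0 * k, 0, 0]) for k in range(5)]
        g = hbond_graph(_dimer_frame(waters), params)
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_prefiltered_equals_exhaustive(self, params, seed):
        frame = make_box(50, 12.0, seed=seed)
        g = hbond_graph(frame, params)
        got = {tuple(sorted(e)) for e in g.edges}
        want = exhaustive_hbond_edges(frame, params.hbond_threshold,
                                      params.distance_prefilter)
        assert got == want

    @pytest.mark.parametrize("seed", [3, 4])
    def test_wide_prefilter_equals_energy_only_graph(self, seed):
        # near-linear pairs can stay below -2.25 kcal/mol out to ~4.0 A
        # O-O, so the energy-only equivalence needs a prefilter >= 4.0 A
        params = PotentialParams(distance_prefilter=4.2)
        frame = make_box(50, 12.0, seed=seed)
        got = {tuple(sorted(e)) for e in hbond_graph(frame, params).edges}
        assert got == exhaustive_energy_only_edges(frame,
                                                   params.hbond_threshold)

    def test_graph_invariant_under_lattice_translation(self, params):
        frame = make_box(30, 11.0, seed=5)
        base = {tuple(sorted(e)) for e in hbond_graph(frame, params).edges}
        shift = np.array([11.0, -22.0, 11.0])
        moved = Frame(index=0, o=frame.o + shift, h1=frame.h1 + shift,
                      h2=frame.h2 + shift, box=frame.box)
        assert {tuple(sorted(e)) for e in hbond_graph(moved, params).edges} == base


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"A": -1.0},
            {"hbond_threshold": 0.5},
            {"q_o": -0.8, "q_h": 0.5},
            {"distance_prefilter": 3.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PotentialParams(**kwargs)


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
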