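"""Voxel grids and ligand/TWN shape similarity."""

import numpy as np
import pytest

from twnkit.errors import LigandError, TwnError
from twnkit.fixtures import make_ring, make_toy_ligand
from twnkit.io import Frame, LigandModel
from twnkit.rings import WaterRing
from twnkit.shape import (
    OccupancyGrid,
    grid_spec_for,
    proximal_rings,
    shape_similarity,
    voxelize_ligand,
    voxelize_twn,
)


def _ring_frame(index, *rings_args):
    waters = []
    rings = []
    for size, center in rings_args:
        start = len(waters)
        waters.extend(make_ring(size, center=center))
        rings.append(WaterRing(members=tuple(range(start, start + size)),
                               frame_index=index))
    frame = Frame(
        index=index,
        o=np.array([w.o_pos for w in waters]),
        h1=np.array([w.h1_pos for w in waters]),
        h2=np.array([w.h2_pos for w in waters]),
    )
    return frame, rings


class TestProximalRings:
    @pytest.mark.parametrize(
        "offset,kept",
        [(1.5, True), (2.0, True), (2.5, False)],  # <=, boundary, >
    )
    def test_com_cutoff_boundary(self, offset, kept):
        lig = LigandModel(name="atom", elements=["C"], coords=[[0.0, 0.0, 0.0]],
                          regions=["head"])
        frame, rings = _ring_frame(0, (3, (0.0, 0.0, offset)))
        got = proximal_rings(rings, [frame], lig, com_cutoff=2.0)
        assert (len(got) == 1) is kept

    def test_distance_is_to_heavy_atoms_only(self):
        lig = LigandModel(name="ch", elements=["H", "C"],
                          coords=[[0.0, 0.0, 1.0], [0.0, 0.0, 4.0]],
                          regions=["head", "head"])
        frame, rings = _ring_frame(0, (3, (0.0, 0.0, 2.5)))
        # 1.5 A from the hydrogen but also 1.5 A from the carbon -> kept;
        # move the carbon away and the ring must drop despite the near H
        assert len(proximal_rings(rings, [frame], lig)) == 1
        lig_far = LigandModel(name="ch", elements=["H", "C"],
                              coords=[[0.0, 0.0, 1.0], [0.0, 0.0, 9.0]],
                              regions=["head", "head"])
        assert proximal_rings(rings, [frame], lig_far) == []


class TestVoxelization:
    def test_single_carbon_sphere_volume(self):
        lig = LigandModel(name="c", elements=["C"], coords=[[0.0, 0.0, 0.0]],
                          regions=["head"])
        grid = voxelize_ligand(lig, "whole", spacing=0.5)
        got = grid.n_occupied * 0.5**3
        want = 4.0 / 3.0 * np.pi * 1.7**3
        assert abs(got - want) / want < 0.15

    def test_single_water_sphere_volume(self):
        lig = make_toy_ligand()
        grid = grid_spec_for(lig, spacing=0.5)
        frame, rings = _ring_frame(0, (3, (12.5, 0.0, 0.0)))
        one = WaterRing(members=(0,), frame_index=0)  # degenerate: one oxygen
        twn = voxelize_twn([one], [frame], grid, water_radius=1.4)
        got = twn.n_occupied * 0.5**3
        want = 4.0 / 3.0 * np.pi * 1.4**3
        assert abs(got - want) / want < 0.15

    def test_region_grid_is_subset_of_whole(self, rod_ligand):
        grid = grid_spec_for(rod_ligand)
        whole = voxelize_ligand(rod_ligand, "whole", grid=grid)
        head = voxelize_ligand(rod_ligand, "head", grid=grid)
        assert not np.any(head.occupied & ~whole.occupied)
        assert head.n_occupied < whole.n_occupied

    def test_empty_scope_rejected(self, rod_ligand):
        lig = LigandModel(name="nohead", elements=["C"], coords=[[0, 0, 0]],
                          regions=["tail"])
        with pytest.raises(LigandError):
            voxelize_ligand(lig, "head")

    def test_zero_rings_empty_grid(self, rod_ligand):
        grid = grid_spec_for(rod_ligand)
        twn = voxelize_twn([], {}, grid)
        assert twn.n_occupied == 0

    def test_duplicated_ring_idempotent(self, rod_ligand):
        grid = grid_spec_for(rod_ligand)
        f0, r0 = _ring_frame(0, (4, (12.5, 0.0, 0.0)))
        f1, r1 = _ring_frame(1, (4, (12.5, 0.0, 0.0)))
        once = voxelize_twn(r0, [f0], grid)
        twice = voxelize_twn(r0 + r1, [f0, f1], grid)
        assert np.array_equal(once.occupied, twice.occupied)


class TestShapeSimilarity:
    def _grids(self):
        occ = np.zeros((4, 4, 4), dtype=bool)
        occ[:2] = True
        lig = OccupancyGrid(origin=[0, 0, 0], spacing=0.5, occupied=occ)
        return lig

    def test_identity_is_100(self):
        lig = self._grids()
        same = OccupancyGrid(origin=[0, 0, 0], spacing=0.5,
                             occupied=lig.occupied.copy())
        assert shape_similarity(lig, same).percent == pytest.approx(100.0)

    def test_disjoint_is_0(self):
        lig = self._grids()
        other = OccupancyGrid(origin=[0, 0, 0], spacing=0.5,
                              occupied=~lig.occupied)
        assert shape_similarity(lig, other).percent == pytest.approx(0.0)

    def test_half_coverage_is_50(self):
        lig = self._grids()
        half = np.zeros_like(lig.occupied)
        half[0] = True  # exactly half of lig's occupied voxels
        twn = OccupancyGrid(origin=[0, 0, 0], spacing=0.5, occupied=half)
        assert shape_similarity(lig, twn).percent == pytest.approx(50.0)

    def test_tanimoto_mode(self):
        lig = self._grids()
        half = np.zeros_like(lig.occupied)
        half[0] = True
        twn = OccupancyGrid(origin=[0, 0, 0], spacing=0.5, occupied=half)
        # |I| = 32, |U| = 64
        assert shape_similarity(lig, twn, mode="tanimoto").percent == \
            pytest.approx(50.0)

    def test_empty_ligand_grid_rejected(self):
        lig = OccupancyGrid(origin=[0, 0, 0], spacing=0.5,
                            occupied=np.zeros((2, 2, 2), dtype=bool))
        twn = OccupancyGrid(origin=[0, 0, 0], spacing=0.5,
                            occupied=np.ones((2, 2, 2), dtype=bool))
        with pytest.raises(TwnError):
            shape_similarity(lig, twn)

    def test_incongruent_grids_rejected(self):
        a = OccupancyGrid(origin=[0, 0, 0], spacing=0.5,
                          occupied=np.ones((2, 2, 2), dtype=bool))
        b = OccupancyGrid(origin=[0, 0, 0], spacing=0.5,
                          occupied=np.ones((3, 2, 2), dtype=bool))
        with pytest.raises(TwnError):
            shape_similarity(a, b)

    def test_adding_rings_never_decreases_coverage(self, rod_ligand):
        grid = grid_spec_for(rod_ligand)
        lig_grid = voxelize_ligand(rod_ligand, "whole", grid=grid)
        centers = [(12.5, 0.0, 1.0), (10.0, 0.5, -1.0), (5.0, -0.5, 1.0),
                   (15.0, 0.0, 1.5)]
        frame, rings = _ring_frame(0, *[(3, c) for c in centers])
        prev = -1.0
        for k in range(len(rings) + 1):
            twn = voxelize_twn(rings[:k], [frame], grid)
            pct = shape_similarity(lig_grid, twn).percent
            assert pct >= prev
            prev = pct

    def test_joint_rotation_changes_score_little(self, rod_ligand):
        from twnkit.fixtures import _random_rotation

        frame, rings = _ring_frame(0, (5, (12.5, 0.0, 1.0)),
                                   (3, (5.0, 1.0, -1.0)))
        grid = grid_spec_for(rod_ligand)
        lig_grid = voxelize_ligand(rod_ligand, "whole", grid=grid)
        twn = voxelize_twn(rings, [frame], grid)
        base = shape_similarity(lig_grid, twn).percent

        rot = _random_rotation(np.random.default_rng(11))
        lig_r = LigandModel(
            name="r", elements=rod_ligand.elements,
            coords=rod_ligand.coords @ rot.T, regions=rod_ligand.regions,
            lprime=rod_ligand.lprime,
        )
        frame_r = Frame(index=0, o=frame.o @ rot.T, h1=frame.h1 @ rot.T,
                        h2=frame.h2 @ rot.T)
        grid_r = grid_spec_for(lig_r)
        lig_grid_r = voxelize_ligand(lig_r, "whole", grid=grid_r)
        twn_r = voxelize_twn(rings, [frame_r], grid_r)
        rotated = shape_similarity(lig_grid_r, twn_r).percent
        assert abs(rotated - base) < 3.0
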