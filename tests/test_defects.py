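"""Packing-defect grid, clustering, and the exponential size-constant fit."""

import math

import numpy as np
import pytest

from ldtk import (
    Frame,
    Leaflet,
    build_defect_grid,
    build_system,
    cluster_defects,
    default_role_map,
    fit_defect_constant,
    label_grid,
    prob_ge,
    prob_ge_ratio,
    sample_defect_sizes,
    size_distribution,
)
from ldtk.defects import CELL_CODE, HALF_DIAGONAL_PLANAR, HALF_DIAGONAL_PRINTED

from oracles import coverage_oracle, flood_fill_sizes


def tiny_leaflet(extra=(), box=(4.0, 4.0, 10.0)):
    """One TOP leaflet: a few PLs with P at z=8 plus extra atoms.

    ``extra`` entries are (resname, atom_names, coords nm).
    """
    names, resnames, resids, coords = [], [], [], []
    rid = 0
    for x, y in [(1.0, 1.0), (3.0, 1.0), (1.0, 3.0), (3.0, 3.0)]:
        rid += 1
        names += ["P"]
        resnames += ["PLM"]
        resids += [rid]
        coords += [[x, y, 8.0]]
    for resname, anames, acoords in extra:
        rid += 1
        names += list(anames)
        resnames += [resname] * len(anames)
        resids += [rid] * len(anames)
        coords += [list(c) for c in acoords]
    system = build_system(names, resnames, resids, default_role_map())
    from ldtk import MoleculeClass

    for m in system.molecules_of_class(MoleculeClass.PL):
        system.leaflets[m] = Leaflet.TOP
    return system, Frame(np.array(coords, float), np.array(box), 0.0)


def test_exposed_acyl_carbon_covers_a_disc():
    # one PL acyl carbon at the centre, everything else far away
    system, frame = tiny_leaflet(extra=[("PLM", ["C1"], [[2.0, 2.0, 7.5]])])
    grid = build_defect_grid(system, frame, Leaflet.TOP)
    carbon = system.n_atoms - 1
    reach = system.radii[carbon] + HALF_DIAGONAL_PRINTED
    mask_oracle = coverage_oracle(
        np.array([[20.0, 20.0]]), np.array([reach]), frame.box[:2] * 10, 40, 40
    )
    got = grid.types == CELL_CODE["PL_ACYL"]
    # cells covered by the P heads are HEAD, not defect
    assert np.array_equal(got, mask_oracle & ~(grid.types == CELL_CODE["HEAD"]))
    assert got.sum() > 0


def test_head_coverage_beats_depth():
    # acyl carbon sits ABOVE a head atom in the same column: still HEAD
    system, frame = tiny_leaflet(
        extra=[("PLM", ["C1"], [[1.0, 1.0, 9.0]])]
    )
    grid = build_defect_grid(system, frame, Leaflet.TOP)
    ix, iy = 10, 10  # cell containing (1.0, 1.0) nm at 1 Å spacing
    assert grid.types[ix, iy] == CELL_CODE["HEAD"]


def test_topmost_atom_decides_type():
    # TG glycerol oxygen above a CHYO tail carbon in the same cell
    system, frame = tiny_leaflet(
        extra=[
            ("CHY", ["O1", "O2", "T1"], [[2.0, 2.0, 5.5], [2.0, 2.0, 5.4], [2.0, 2.0, 7.0]]),
            ("TGL", ["E1", "E2", "E3", "G1", "G2", "G3"],
             [[2.0, 2.0, 7.6]] + [[2.0, 2.0, 5.0]] * 5),
        ]
    )
    grid = build_defect_grid(system, frame, Leaflet.TOP)
    assert grid.types[20, 20] == CELL_CODE["TG_GLYC"]


def test_depth_threshold_excludes_deep_atoms():
    # mean P z = 8 nm -> z_thr = 6 nm; a carbon at 5.9 nm is not a candidate
    system, frame = tiny_leaflet(extra=[("PLM", ["C1"], [[2.0, 2.0, 5.9]])])
    grid = build_defect_grid(system, frame, Leaflet.TOP)
    assert grid.z_thr == pytest.approx(60.0)
    assert not (grid.types == CELL_CODE["PL_ACYL"]).any()
    system, frame = tiny_leaflet(extra=[("PLM", ["C1"], [[2.0, 2.0, 6.1]])])
    grid = build_defect_grid(system, frame, Leaflet.TOP)
    assert (grid.types == CELL_CODE["PL_ACYL"]).any()


def test_bottom_leaflet_mirrors_sign():
    from ldtk import MoleculeClass

    # for BOTTOM the threshold sits ABOVE the heads and "outermost" means
    # the lowest z: a carbon below the heads is exposed ...
    system, frame = tiny_leaflet(extra=[("PLM", ["C1"], [[2.0, 2.0, 7.5]])])
    for m in system.molecules_of_class(MoleculeClass.PL):
        system.leaflets[m] = Leaflet.BOTTOM
    grid = build_defect_grid(system, frame, Leaflet.BOTTOM)
    assert grid.z_thr == pytest.approx(100.0)
    assert (grid.types == CELL_CODE["PL_ACYL"]).any()
    # ... while a carbon beyond mean-P-z + depth is not a candidate
    system, frame = tiny_leaflet(extra=[("PLM", ["C1"], [[2.0, 2.0, 10.1]])],
                                 box=(4.0, 4.0, 12.0))
    for m in system.molecules_of_class(MoleculeClass.PL):
        system.leaflets[m] = Leaflet.BOTTOM
    grid = build_defect_grid(system, frame, Leaflet.BOTTOM)
    assert not (grid.types == CELL_CODE["PL_ACYL"]).any()


def test_half_diagonal_conventions_differ():
    system, frame = tiny_leaflet(extra=[("PLM", ["C1"], [[2.0, 2.0, 7.5]])])
    g1 = build_defect_grid(system, frame, Leaflet.TOP,
                           half_diagonal=HALF_DIAGONAL_PRINTED)
    g2 = build_defect_grid(system, frame, Leaflet.TOP,
                           half_diagonal=HALF_DIAGONAL_PLANAR)
    n1 = int((g1.types == CELL_CODE["PL_ACYL"]).sum())
    n2 = int((g2.types == CELL_CODE["PL_ACYL"]).sum())
    assert n1 > n2 > 0


def test_corner_touching_patches_connectivity():
    mask = np.zeros((10, 10), dtype=bool)
    mask[2:4, 2:4] = True
    mask[4:6, 4:6] = True  # shares only the corner (4,4)-(3,3)
    _, n4 = label_grid(mask, connectivity=4, periodic=True)
    _, n8 = label_grid(mask, connectivity=8, periodic=True)
    assert n4 == 2
    assert n8 == 1


def test_periodic_wrap_merges_components():
    mask = np.zeros((8, 8), dtype=bool)
    mask[0, 3] = mask[-1, 3] = True
    labels, n = label_grid(mask, connectivity=4, periodic=True)
    assert n == 1
    _, n_open = label_grid(mask, connectivity=4, periodic=False)
    assert n_open == 2
    # diagonal wrap across the corner only merges under 8-connectivity
    corner = np.zeros((6, 6), dtype=bool)
    corner[0, 0] = corner[-1, -1] = True
    assert label_grid(corner, 4, True)[1] == 2
    assert label_grid(corner, 8, True)[1] == 1


def test_label_grid_matches_flood_fill_on_random_grids():
    rng = np.random.default_rng(12)
    for k in range(60):
        mask = rng.random((20, 20)) < rng.uniform(0.2, 0.7)
        conn = 4 if k % 2 == 0 else 8
        labels, n = label_grid(mask, connectivity=conn, periodic=True)
        got = sorted(np.bincount(labels.ravel())[1:].tolist()) if n else []
        want = sorted(flood_fill_sizes(mask, conn, periodic=True))
        assert got == want


def test_size_distribution_normalized():
    vals, probs = size_distribution([1, 1, 2, 2, 2, 5])
    assert vals.tolist() == [1.0, 2.0, 5.0]
    assert probs.sum() == pytest.approx(1.0)
    assert probs.tolist() == pytest.approx([2 / 6, 3 / 6, 1 / 6])


def test_fit_recovers_exact_exponential_law():
    pi_true = 18.0
    sizes = np.repeat(np.arange(1, 120),
                      np.round(1e6 * np.exp(-np.arange(1, 120) / pi_true)).astype(int))
    fit = fit_defect_constant(sizes, fit_range=(1, 119), weighted=False)
    assert fit.pi == pytest.approx(pi_true, rel=1e-3)
    assert fit.r_squared > 0.999999


def test_fit_error_modes():
    with pytest.raises(ValueError, match="no clusters"):
        fit_defect_constant([])
    with pytest.raises(ValueError, match="single-size"):
        fit_defect_constant([7.0] * 50)
    growing = np.repeat([10, 20, 30], [5, 50, 500])
    with pytest.raises(ValueError, match="non-decaying"):
        fit_defect_constant(growing, fit_range=(1, 40))


def test_prob_ge_and_ratio():
    sizes_a = [10, 60, 70, 80]
    sizes_b = [10, 20, 30, 60]
    assert prob_ge(sizes_a) == pytest.approx(0.75)
    assert prob_ge_ratio(sizes_a, sizes_b) == pytest.approx(3.0)


def test_defect_statistics_translation_invariant():
    from ldtk.synth import SyntheticSpec, generate_defect_leaflet

    spec = SyntheticSpec(seed=21, box=(5.0, 5.0, 5.0), n_layers=1,
                         core_half_thickness=1.0, n_pl_per_leaflet=20,
                         water_density_core=0.0, water_density_slab=0.0,
                         planted_defects=[("TOP", "TG_ACYL", 9, 3),
                                          ("TOP", "PL_ACYL", 6, 2)])
    system, frame, truth = generate_defect_leaflet(spec)
    base = sorted(c.size for c in cluster_defects(
        build_defect_grid(system, frame, Leaflet.TOP)))
    # the 1 Å grid is anchored to the box, so invariance holds for shifts
    # commensurate with the cell size
    for shift in ([1.3, 0.0], [0.0, 2.9], [3.2, 4.6]):
        coords = frame.coords.copy()
        coords[:, 0] = np.mod(coords[:, 0] + shift[0], frame.box[0])
        coords[:, 1] = np.mod(coords[:, 1] + shift[1], frame.box[1])
        moved = Frame(coords, frame.box, frame.time)
        got = sorted(c.size for c in cluster_defects(
            build_defect_grid(system, moved, Leaflet.TOP)))
        assert got == pytest.approx(base)


def test_sampled_sizes_tail_matches_discrete_law():
    pi_true = 20.0
    n = 100_000
    sizes = sample_defect_sizes(pi_true, n, seed=77)
    # discretized exponential (geometric, support >= 1): P(N >= t) = e^{-(t-1)/pi}
    t = 50.0
    expected = math.exp(-(t - 1.0) / pi_true)
    se = math.sqrt(expected * (1 - expected) / n)
    assert abs(prob_ge(sizes, t) - expected) < 4 * se
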