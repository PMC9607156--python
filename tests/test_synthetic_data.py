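"""Synthetic generator: planted ground truth and determinism."""

import math

import numpy as np
import pytest

from ldtk import (
    Leaflet,
    MoleculeClass,
    SyntheticSpec,
    classify_frame,
    dihedral_energy,
    generate_core,
    generate_defect_leaflet,
    generate_trilayer,
    hydration,
    molecular_axes,
    nematic_order,
    sample_axes,
    sample_defect_sizes,
    solve_axial_concentration,
    synthetic_pes,
    trilayer_ground_truth,
)
from ldtk.defects import cluster_defects, build_defect_grid
from ldtk.dihedrals import DihedralModel, DihedralTerm
from ldtk.surface import apl

from conftest import small_spec


def core_spec(**overrides):
    base = dict(seed=7, box=(6.0, 6.0, 10.0), n_chyo=100, n_tg=10,
                n_pl_per_leaflet=0, water_density_core=0.0,
                water_density_slab=0.0)
    base.update(overrides)
    return SyntheticSpec(**base)


def test_perfect_alignment_gives_exact_unity_order():
    system, frame = generate_core(core_spec(target_S=1.0))
    res = nematic_order(molecular_axes(system, frame), director=[0, 0, 1])
    assert res.S == pytest.approx(1.0, abs=1e-12)


def test_isotropic_target_within_sampling_error():
    n = 400
    system, frame = generate_core(core_spec(target_S=0.0, n_chyo=n))
    res = nematic_order(molecular_axes(system, frame), director=[0, 0, 1])
    assert abs(res.S) <= 3.0 / math.sqrt(n)


def test_deterministic_updown_is_exact():
    system, frame = generate_core(core_spec(updown_ratio=0.5, n_chyo=100,
                                            n_layers=2, target_S=1.0))
    axes = molecular_axes(system, frame)
    signs = axes.vectors[0][:, 2] > 0
    assert int(signs.sum()) == 50  # 25 up per 50-molecule layer, exactly


def test_axial_sampler_hits_target_order():
    rng = np.random.default_rng(0)
    v = sample_axes(rng, 200_000, 0.81)
    s = float(np.mean(1.5 * v[:, 2] ** 2 - 0.5))
    assert s == pytest.approx(0.81, abs=0.01)
    assert solve_axial_concentration(0.0) == pytest.approx(0.0, abs=1e-6)


def test_planted_apl_example():
    spec = small_spec(box=(10.0, 10.0, 14.0), n_pl_per_leaflet=100,
                      surf_tg_fraction=0.0, water_density_slab=0.0)
    system, frame = generate_trilayer(spec)
    a = apl(system, [frame], Leaflet.TOP, "PL_ONLY", equilibration=0.0)
    assert a.mean == pytest.approx(1.00, abs=1e-12)


def test_planted_surf_tg_count():
    spec = small_spec(n_tg=40, surf_tg_fraction=0.05)
    system, frame = generate_trilayer(spec)
    _, surf, _ = classify_frame(system, frame)
    assert int(surf.sum()) == 2


def test_zero_core_water_gives_zero_hydration():
    spec = small_spec(water_density_core=0.0)
    system, frame = generate_trilayer(spec)
    assert hydration(system, frame, region="CORE") == pytest.approx(0.0, abs=0.0)


def test_ground_truth_water_density_is_recovered_exactly():
    spec = small_spec(water_density_core=0.004)
    truth = trilayer_ground_truth(spec)
    system, frame = generate_trilayer(spec)
    assert hydration(system, frame) == pytest.approx(
        truth["core_water_density"], rel=1e-12
    )


def test_seed_determinism():
    s1, f1 = generate_trilayer(small_spec(seed=5))
    s2, f2 = generate_trilayer(small_spec(seed=5))
    s3, f3 = generate_trilayer(small_spec(seed=6))
    assert np.array_equal(f1.coords, f2.coords)
    assert not np.array_equal(f1.coords, f3.coords)
    assert s1.n_atoms == s2.n_atoms


def test_invalid_specs_raise():
    with pytest.raises(ValueError):
        SyntheticSpec(target_S=1.2).validate()
    with pytest.raises(ValueError):
        SyntheticSpec(surf_tg_fraction=-0.1).validate()
    with pytest.raises(ValueError, match="area per lipid"):
        SyntheticSpec(box=(4.0, 4.0, 16.0), n_pl_per_leaflet=135).validate()
    with pytest.raises(ValueError, match="fit"):
        SyntheticSpec(n_layers=6, layer_spacing=3.45, box=(9, 9, 16)).validate()


def defect_spec(entries, seed=0, box_xy=5.0):
    return SyntheticSpec(seed=seed, box=(box_xy, box_xy, 5.0), n_layers=1,
                         core_half_thickness=1.0, n_pl_per_leaflet=20,
                         water_density_core=0.0, water_density_slab=0.0,
                         planted_defects=entries)


def test_single_patch_recovered_exactly():
    system, frame, truth = generate_defect_leaflet(
        defect_spec([("TOP", "PL_ACYL", 25, 1)])
    )
    assert truth == [("PL_ACYL", 25)]
    grid = build_defect_grid(system, frame, Leaflet.TOP)
    clusters = [c for c in cluster_defects(grid) if c.cells.size]
    assert len(clusters) == 1
    assert clusters[0].defect_type == "PL_ACYL"
    assert clusters[0].size == pytest.approx(25.0)


def test_full_head_coverage_means_zero_defects():
    system, frame, truth = generate_defect_leaflet(defect_spec([]))
    assert truth == []
    grid = build_defect_grid(system, frame, Leaflet.TOP)
    assert not grid.defect_mask().any()


def test_planted_inventory_multiple_types():
    entries = [("TOP", "TG_GLYC", 9, 3), ("TOP", "CHYO_SIDE", 16, 2),
               ("TOP", "TG_ACYL", 4, 4)]
    system, frame, truth = generate_defect_leaflet(defect_spec(entries, box_xy=7.0))
    grid = build_defect_grid(system, frame, Leaflet.TOP)
    got = sorted(
        (c.defect_type, int(round(c.size))) for c in cluster_defects(grid)
    )
    assert got == sorted(truth)


def test_sample_defect_sizes_mean_matches_geometric_law():
    pi_true = 20.0
    sizes = sample_defect_sizes(pi_true, 100_000, seed=42)
    mean_law = 1.0 / (1.0 - math.exp(-1.0 / pi_true))
    assert np.mean(sizes) == pytest.approx(mean_law, rel=0.01)
    assert sizes.min() >= 1


def test_synthetic_pes_matches_model_energy():
    terms = [(1, 1.5, 0.0), (3, 0.75, 180.0)]
    phi = np.linspace(-180, 180, 24, endpoint=False)
    scan = synthetic_pes(terms, phi)
    model = DihedralModel([DihedralTerm(n, k, d) for n, k, d in terms])
    assert np.allclose(scan.target_energy, dihedral_energy(model, phi))
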