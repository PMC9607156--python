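"""Orientational/translational order: S, layering, S_CD, RDFs."""

import math

import numpy as np
import pytest

from ldtk import (
    Frame,
    MoleculeClass,
    Role,
    SyntheticSpec,
    assign_layers,
    generate_core,
    layer_spacing,
    molecular_axes,
    nematic_order,
    number_density_profile,
    rdf2d,
    rdf3d,
    tail_order,
    updown_fractions,
)
from ldtk.order import Profile

from conftest import small_spec
from test_synthetic_data import core_spec


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def test_perpendicular_vectors_give_minus_half():
    rng = np.random.default_rng(1)
    phi = rng.uniform(0, 2 * np.pi, 500)
    v = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
    res = nematic_order(v, director=[0.0, 0.0, 1.0])
    assert res.S == pytest.approx(-0.5, abs=1e-12)


def test_sign_flip_invariance():
    rng = np.random.default_rng(2)
    v = rng.normal(size=(300, 3))
    flipped = v * np.where(rng.random(300) < 0.5, -1.0, 1.0)[:, None]
    a = nematic_order(v, director=[0, 0, 1]).S
    b = nematic_order(flipped, director=[0, 0, 1]).S
    assert a == pytest.approx(b, abs=1e-12)


def test_auto_director_recovers_planted_axis():
    rng = np.random.default_rng(3)
    from ldtk import sample_axes

    v = sample_axes(rng, 5000, 0.85)
    r = rotation_matrix([1, 1, 0], 0.7)
    res = nematic_order(v @ r.T, director="auto")
    planted = r @ np.array([0.0, 0.0, 1.0])
    assert abs(float(res.director @ planted)) > 0.999


def test_auto_rotation_invariance():
    rng = np.random.default_rng(4)
    from ldtk import sample_axes

    v = sample_axes(rng, 2000, 0.7)
    s0 = nematic_order(v, director="auto").S
    for angle in (0.3, 1.1, 2.0):
        r = rotation_matrix([0.2, -1.0, 0.5], angle)
        s1 = nematic_order(v @ r.T, director="auto").S
        assert s1 == pytest.approx(s0, abs=1e-9)


def test_per_frame_series_and_window():
    frames = [np.tile([0.0, 0.0, 1.0], (50, 1)) for _ in range(4)]
    res = nematic_order(frames, director=[0, 0, 1], window_fraction=0.5)
    assert len(res.per_frame_S) == 4
    assert res.window == (2, 4)
    assert res.converged_mean == pytest.approx(1.0)
    assert res.converged_sd == pytest.approx(0.0)


def test_nematic_order_rejects_bad_input():
    with pytest.raises(ValueError):
        nematic_order(np.zeros((5, 3)), director=[0, 0, 1])
    with pytest.raises(ValueError):
        nematic_order(np.empty((0, 3)), director="auto")
    with pytest.raises(ValueError):
        nematic_order(np.ones((5, 3)), director="principal")


def test_layer_spacing_recovers_planted_value():
    spec = core_spec(n_layers=3, layer_spacing=2.8, box=(6.0, 6.0, 12.0),
                     n_chyo=150, target_S=1.0, position_jitter=0.0)
    system, frame = generate_core(spec)
    prof = number_density_profile(system, frame, Role.ESTER_O,
                                  MoleculeClass.CHYO, bin_width=0.1)
    spacing, sd, peaks = layer_spacing(prof)
    assert len(peaks) == 3
    assert spacing == pytest.approx(2.8, abs=0.1)


def test_layer_spacing_needs_two_peaks():
    edges = np.arange(0.0, 5.1, 0.1)
    vals = np.zeros(len(edges) - 1)
    vals[25] = 1.0
    with pytest.raises(ValueError, match="2 peaks"):
        layer_spacing(Profile(edges, vals))


def test_updown_fractions_per_layer():
    spec = core_spec(n_layers=2, n_chyo=100, target_S=1.0,
                     updown_ratio=0.3, position_jitter=0.0)
    system, frame = generate_core(spec)
    axes = molecular_axes(system, frame)
    prof = number_density_profile(system, frame, Role.ESTER_O,
                                  MoleculeClass.CHYO, bin_width=0.1)
    _, _, peaks = layer_spacing(prof)
    layers = assign_layers(system, frame, peaks)
    ud = updown_fractions(axes, layers)
    assert set(ud) == {0, 1}
    for up, down in ud.values():
        assert up + down == pytest.approx(1.0)
        assert up == pytest.approx(0.3, abs=0.03)  # Bresenham-exact per layer


def test_tail_order_planted_perpendicular_hydrogens(trilayer):
    system, frame = trilayer
    # PL pseudo-molecules carry C–H bonds exactly perpendicular to z
    scd = tail_order(system, frame, MoleculeClass.PL)
    assert np.allclose(scd, -0.5, atol=1e-12)


def test_rdf3d_uniform_gas_is_flat():
    # ideal gas: uniform random CHYO "ring" sites in a cubic box
    from ldtk.core import build_system, default_role_map

    rng = np.random.default_rng(5)
    n = 300
    names, resnames, resids, coords = [], [], [], []
    for i in range(n):
        p = rng.uniform(0, 8.0, 3)
        for j, off in enumerate([[0, 0, 0.01], [0, 0, -0.01], [0.01, 0, 0]]):
            names.append(f"R{j + 1}")
            resnames.append("CHY")
            resids.append(i + 1)
            coords.append(p + off)
        for j, nm in enumerate(["O1", "O2"]):
            names.append(nm)
            resnames.append("CHY")
            resids.append(i + 1)
            coords.append(p + [0, 0.01 * (j + 1), 0])
    system = build_system(names, resnames, resids, default_role_map())
    frame = Frame(np.array(coords), np.array([8.0, 8.0, 8.0]), 0.0)
    g = rdf3d(system, frame, r_max=3.0, dr=0.25)
    tail = g.values[g.centers > 0.5]
    assert np.all(np.abs(tail - 1.0) < 0.35)
    assert np.mean(tail) == pytest.approx(1.0, abs=0.1)


def test_rdf3d_r_max_guard(trilayer):
    system, frame = trilayer
    with pytest.raises(ValueError, match="half"):
        rdf3d(system, frame, r_max=100.0)


def test_rdf2d_same_layer_pairs():
    spec = core_spec(n_layers=2, n_chyo=100, target_S=1.0, position_jitter=0.0)
    system, frame = generate_core(spec)
    prof = number_density_profile(system, frame, Role.ESTER_O,
                                  MoleculeClass.CHYO, bin_width=0.1)
    _, _, peaks = layer_spacing(prof)
    layers = assign_layers(system, frame, peaks)
    g = rdf2d(system, frame, layers, r_max=2.5, dr=0.05)
    assert g.values.shape == (50,)
    assert np.all(g.values >= 0)
    # lattice construction: strong first-neighbour peak above the mean
    assert g.values.max() > 2.0
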