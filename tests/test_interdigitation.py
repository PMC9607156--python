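"""Density profiles, overlap parameter, lambda_ov, relative density,
hydration."""

import numpy as np
import pytest

from ldtk import (
    Leaflet,
    MoleculeClass,
    classify,
    generate_trilayer,
    hydration,
    interdigitation_analysis,
    lambda_ov,
    mass_density_profile,
    overlap_parameter,
    relative_density,
    species_profiles,
)
from ldtk.interdig import AMU_PER_NM3
from ldtk.order import Profile

from conftest import small_spec


def box_profile(edges, lo, hi, height=1.0):
    centers = 0.5 * (np.asarray(edges)[1:] + np.asarray(edges)[:-1])
    vals = np.where((centers >= lo) & (centers < hi), height, 0.0)
    return Profile(np.asarray(edges, float), vals, units="kg/m^3")


def test_mass_conservation_exact(trilayer):
    system, frame = trilayer
    for mclass in (None, MoleculeClass.CHYO, MoleculeClass.WATER):
        prof = mass_density_profile(system, frame, mclass=mclass, bin_width=0.13)
        sel = system.select(mclass=mclass)
        total = float(np.sum(system.masses[sel])) * AMU_PER_NM3
        integral = float(np.sum(prof.values * prof.widths)) * frame.box[0] * frame.box[1]
        assert integral == pytest.approx(total, rel=1e-12)


def test_overlap_parameter_limits():
    edges = np.arange(0.0, 5.05, 0.1)
    a = box_profile(edges, 1.0, 3.0, 800.0)
    same = overlap_parameter(a, a)
    inside = (a.centers >= 1.0) & (a.centers < 3.0)
    assert np.all(same.values[inside] == 1.0)
    assert np.all(same.values[~inside] == 0.0)
    disjoint = overlap_parameter(a, box_profile(edges, 3.5, 4.5, 800.0))
    assert np.all(disjoint.values == 0.0)


def test_overlap_parameter_symmetry_and_scale_invariance():
    edges = np.arange(0.0, 4.05, 0.05)
    rng = np.random.default_rng(9)
    a = Profile(edges, rng.random(len(edges) - 1), units="kg/m^3")
    b = Profile(edges, rng.random(len(edges) - 1), units="kg/m^3")
    ab = overlap_parameter(a, b).values
    ba = overlap_parameter(b, a).values
    assert np.allclose(ab, ba, atol=1e-15)
    scaled = overlap_parameter(
        Profile(edges, 7.3 * a.values), Profile(edges, 7.3 * b.values)
    ).values
    assert np.allclose(scaled, ab, atol=1e-12)


def test_overlap_requires_matching_edges():
    a = box_profile(np.arange(0, 5.05, 0.1), 1, 3)
    b = box_profile(np.arange(0, 5.025, 0.05), 1, 3)
    with pytest.raises(ValueError, match="bin edges"):
        overlap_parameter(a, b)


def test_lambda_ov_rectangular_window_is_exact():
    edges = np.arange(0.0, 8.05, 0.1)
    a = box_profile(edges, 2.0, 5.5, 640.0)
    assert lambda_ov(overlap_parameter(a, a)) == pytest.approx(3.5, abs=1e-12)


def test_lambda_ov_matches_fine_grid_riemann_oracle():
    # smooth overlapping gaussians; oracle = 10x finer midpoint sum
    def gauss(z, mu, sig):
        return np.exp(-0.5 * ((z - mu) / sig) ** 2)

    def lam(width):
        edges = np.arange(0.0, 10.0 + width / 2, width)
        c = 0.5 * (edges[1:] + edges[:-1])
        nl = Profile(edges, 900 * gauss(c, 4.0, 1.0))
        pl = Profile(edges, 700 * gauss(c, 6.0, 0.8))
        return lambda_ov(overlap_parameter(nl, pl))

    assert lam(0.1) == pytest.approx(lam(0.01), rel=5e-3)


def test_species_profiles_split_and_sum(trajectory):
    system, frames = trajectory
    labels = classify(system, frames)
    profs = species_profiles(system, frames, labels, bin_width=0.1)
    assert set(profs) == {"PL", "CHYO", "CORE_TG", "SURF_TG", "NL"}
    assert np.allclose(
        profs["NL"].values,
        profs["CHYO"].values + profs["CORE_TG"].values + profs["SURF_TG"].values,
        atol=1e-9,
    )
    # SURF TG mass lives above the top tail plane only
    spec = small_spec()
    top_plane = spec.box[2] / 2 + spec.core_half_thickness
    below = profs["SURF_TG"].centers < top_plane - 0.6
    assert np.all(profs["SURF_TG"].values[below] == 0.0)
    assert profs["SURF_TG"].values.sum() > 0


def test_interdigitation_modes(trajectory):
    system, frames = trajectory
    labels = classify(system, frames)
    for mode in ("per_leaflet", "whole_box"):
        res = interdigitation_analysis(system, frames, labels, mode=mode)
        assert res.mode == mode
        assert res.lambda_ov >= 0
        assert len(res.per_frame) == len(frames)
        assert res.species["NL"] == pytest.approx(
            res.species["CHYO"] + 0.0, abs=res.species["CHYO"]
            + res.species["CORE_TG"] + res.species["SURF_TG"] + 1e-9
        )
    with pytest.raises(ValueError, match="mode"):
        interdigitation_analysis(system, frames, labels, mode="bogus")


def test_relative_density_fractions_sum_to_one(trajectory):
    system, frames = trajectory
    labels = classify(system, frames)
    profs = species_profiles(system, frames, labels, bin_width=0.1)
    rel = relative_density(
        {k: profs[k] for k in ("PL", "CHYO", "CORE_TG", "SURF_TG")}
    )
    assert sum(rel.fractions.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(0.0 <= v <= 1.0 for v in rel.fractions.values())
    lo, hi = rel.region
    assert lo < hi


def test_relative_density_explicit_region_and_errors():
    edges = np.arange(0.0, 5.05, 0.1)
    pl = box_profile(edges, 1.0, 3.0, 600.0)
    nl = box_profile(edges, 2.0, 4.0, 600.0)
    rel = relative_density({"PL": pl, "NL": nl}, region=(2.0, 3.0))
    assert rel.fractions["PL"] == pytest.approx(0.5, abs=1e-12)
    with pytest.raises(ValueError, match="PL"):
        relative_density({"NL": nl})
    with pytest.raises(ValueError, match="region"):
        relative_density({"PL": pl, "NL": nl}, region=(4.6, 4.9))


def test_hydration_profile_units(trilayer):
    system, frame = trilayer
    prof = hydration(system, frame, region="PROFILE", bin_width=0.1)
    assert prof.units == "g/cm^3"
    # slab water planted at 0.2 g/cm³ shows up at about that density
    spec = small_spec()
    slab = prof.centers > spec.box[2] / 2 + spec.core_half_thickness + 2.0
    assert prof.values[slab].mean() == pytest.approx(0.2, rel=0.1)
    with pytest.raises(ValueError, match="region"):
        hydration(system, frame, region="SHELL")
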