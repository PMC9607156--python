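"""Density profiles, interdigitation and core hydration.

The degree of interdigitation between the neutral lipids (NL) and the
phospholipids (PL) is quantified by the overlap parameter

    rho_ov(z) = 4 rho_NL(z) rho_PL(z) / (rho_NL(z) + rho_PL(z))^2

which is 1 where the two mass densities are equal and 0 where either
vanishes, and by its integral over z, the overlap distance lambda_ov (nm).
Relative densities rho_species / rho_total inside the PL–NL overlap region
resolve which species actually interdigitates.  Core hydration is the water
mass density between the two PL tail planes.

Mass density is used throughout (kg/m³; hydration in g/cm³).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Frame,
    Leaflet,
    MoleculeClass,
    NEUTRAL_LIPID_CLASSES,
    Role,
    SystemModel,
)
from .order import Profile
from .surface import SurfLabelSeries, pl_tail_mean_z

__all__ = [
    "OverlapProfile",
    "InterdigitationResult",
    "RelativeDensityResult",
    "mass_density_profile",
    "overlap_parameter",
    "lambda_ov",
    "species_profiles",
    "interdigitation_analysis",
    "relative_density",
    "hydration",
]

# 1 amu / nm³ in kg/m³
AMU_PER_NM3 = 1.66053906660


@dataclass
class OverlapProfile(Profile):
    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("overlap parameter must lie in [0, 1]")


@dataclass
class InterdigitationResult:
    lambda_ov: float  # nm, total NL vs PL
    per_frame: np.ndarray  # nm per frame (total NL)
    species: dict  # name -> lambda_ov nm
    mode: str  # "per_leaflet" (summed) or "whole_box"


@dataclass
class RelativeDensityResult:
    fractions: dict  # species name -> mass fraction in the overlap region
    region: tuple[float, float]  # nm


def _zhist(
    system: SystemModel,
    frame: Frame,
    atoms: np.ndarray,
    edges: np.ndarray,
) -> np.ndarray:
    """Mass histogram (kg/m³) of selected atoms along z for one frame."""
    z = np.mod(frame.coords[atoms, 2], frame.box[2])
    w = system.masses[atoms]
    counts, _ = np.histogram(z, bins=edges, weights=w)
    vol = frame.box[0] * frame.box[1] * np.diff(edges)
    return counts / vol * AMU_PER_NM3


def mass_density_profile(
    system: SystemModel,
    frames: Frame | list[Frame],
    mclass: MoleculeClass | tuple | None = None,
    roles: Role | None = None,
    molecules=None,
    bin_width: float = 0.1,
) -> Profile:
    """Frame-averaged mass density (kg/m³) of a selection along z.

    Conservation: sum(rho * dz) * Lx * Ly equals the selected mass exactly
    for every frame subset.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    sel = system.select(mclass=mclass, roles=roles, molecules=molecules)
    if len(sel) == 0:
        raise ValueError("empty selection")
    lz = frames[0].box[2]
    edges = np.arange(0.0, lz + bin_width, bin_width)
    if edges[-1] < lz:
        edges = np.append(edges, lz)
    vals = np.zeros(len(edges) - 1)
    for fr in frames:
        vals += _zhist(system, fr, sel, edges)
    vals /= len(frames)
    return Profile(edges, vals, units="kg/m^3")


def overlap_parameter(rho_nl: Profile, rho_pl: Profile) -> OverlapProfile:
    """Eq.-of-overlap profile: 4 a b / (a + b)²; 0 where both are 0."""
    if len(rho_nl.bin_edges) != len(rho_pl.bin_edges) or not np.allclose(
        rho_nl.bin_edges, rho_pl.bin_edges
    ):
        raise ValueError("profiles must share identical bin edges")
    a, b = rho_nl.values, rho_pl.values
    denom = (a + b) ** 2
    vals = np.divide(4 * a * b, denom, out=np.zeros_like(denom), where=denom > 0)
    return OverlapProfile(rho_nl.bin_edges, vals, units="dimensionless")


def lambda_ov(overlap: OverlapProfile | Profile) -> float:
    """Overlap distance (nm): integral of rho_ov over z.

    Computed as sum(rho_ov * bin width), the exact integral of the binned
    step profile (so a rectangular window of width w integrates to w).
    """
    return float(np.sum(overlap.values * overlap.widths))


def species_profiles(
    system: SystemModel,
    frames: list[Frame],
    labels: SurfLabelSeries | None = None,
    bin_width: float = 0.1,
    pl_leaflet: Leaflet | None = None,
) -> dict[str, Profile]:
    """Frame-averaged mass-density profiles per species.

    Returns profiles keyed PL, CHYO, CORE_TG, SURF_TG, NL (total neutral
    lipid).  The CORE/SURF split of TG follows the per-frame labels; without
    labels all TGs count as CORE_TG.  ``pl_leaflet`` restricts the PL
    profile to one leaflet.
    """
    lz = frames[0].box[2]
    edges = np.arange(0.0, lz + bin_width, bin_width)
    if edges[-1] < lz:
        edges = np.append(edges, lz)
    keys = ["PL", "CHYO", "CORE_TG", "SURF_TG", "NL"]
    acc = {k: np.zeros(len(edges) - 1) for k in keys}

    if pl_leaflet is None:
        pl_atoms = system.select(mclass=MoleculeClass.PL)
    else:
        mols = [
            m for m in system.molecules_of_class(MoleculeClass.PL)
            if system.leaflets.get(m) is pl_leaflet
        ]
        pl_atoms = system.select(molecules=mols)
    chyo_atoms = system.select(mclass=MoleculeClass.CHYO)
    tg_mols = system.molecules_of_class(MoleculeClass.TG)

    for j, fr in enumerate(frames):
        if len(pl_atoms):
            acc["PL"] += _zhist(system, fr, pl_atoms, edges)
        if len(chyo_atoms):
            acc["CHYO"] += _zhist(system, fr, chyo_atoms, edges)
        surf_mols: set[int] = set()
        if labels is not None:
            col = min(j, labels.surf.shape[1] - 1)
            surf_mols = {
                m for i, m in enumerate(labels.molecule_ids) if labels.surf[i, col]
            }
        core_tg = [m for m in tg_mols if m not in surf_mols]
        surf_tg = [m for m in tg_mols if m in surf_mols]
        if core_tg:
            idx = system.select(molecules=core_tg)
            acc["CORE_TG"] += _zhist(system, fr, idx, edges)
        if surf_tg:
            idx = system.select(molecules=surf_tg)
            acc["SURF_TG"] += _zhist(system, fr, idx, edges)
    n = len(frames)
    for k in keys:
        acc[k] /= n
    acc["NL"] = acc["CHYO"] + acc["CORE_TG"] + acc["SURF_TG"]
    return {k: Profile(edges, acc[k], units="kg/m^3") for k in keys}


def interdigitation_analysis(
    system: SystemModel,
    frames: list[Frame],
    labels: SurfLabelSeries | None = None,
    bin_width: float = 0.1,
    mode: str = "per_leaflet",
) -> InterdigitationResult:
    """Overlap distances per species and the total per-frame series.

    ``per_leaflet`` computes lambda_ov of each NL species against each
    leaflet's own PL density and sums the two; ``whole_box`` uses the
    combined PL profile.
    """
    if mode == "per_leaflet":
        leaflets = [Leaflet.TOP, Leaflet.BOTTOM]
    elif mode == "whole_box":
        leaflets = [None]
    else:
        raise ValueError("mode must be per_leaflet or whole_box")

    species = {"CHYO": 0.0, "CORE_TG": 0.0, "SURF_TG": 0.0, "NL": 0.0}
    for lf in leaflets:
        profs = species_profiles(system, frames, labels, bin_width, pl_leaflet=lf)
        for name in species:
            species[name] += lambda_ov(overlap_parameter(profs[name], profs["PL"]))

    per_frame = np.zeros(len(frames))
    for j, fr in enumerate(frames):
        total = 0.0
        for lf in leaflets:
            profs = species_profiles(system, [fr], labels, bin_width, pl_leaflet=lf)
            total += lambda_ov(overlap_parameter(profs["NL"], profs["PL"]))
        per_frame[j] = total
    return InterdigitationResult(
        lambda_ov=species["NL"], per_frame=per_frame, species=species, mode=mode
    )


def relative_density(
    profiles: dict[str, Profile],
    region: tuple[float, float] | str = "AUTO",
    floor_frac: float = 0.01,
) -> RelativeDensityResult:
    """Species mass fractions inside the PL–NL overlap region.

    ``profiles`` must contain a ``PL`` profile; every other key is treated
    as a neutral-lipid species.  The AUTO region is the longest contiguous
    z-range where both the total-NL and the PL density exceed
    ``floor_frac`` of their respective maxima.  Fractions are species mass
    in the region over total (NL + PL) mass and sum to 1.
    """
    if "PL" not in profiles:
        raise ValueError("profiles must include a 'PL' entry")
    pl = profiles["PL"]
    nl_keys = [k for k in profiles if k != "PL"]
    if not nl_keys:
        raise ValueError("no neutral-lipid profiles given")
    nl_total = np.sum([profiles[k].values for k in nl_keys], axis=0)

    if isinstance(region, str):
        if region != "AUTO":
            raise ValueError("region must be (z_lo, z_hi) or 'AUTO'")
        mask = (nl_total > floor_frac * nl_total.max()) & (
            pl.values > floor_frac * pl.values.max()
        )
        if not mask.any():
            raise ValueError("empty overlap region")
        # longest contiguous run
        best, cur, best_len = None, None, 0
        for i, m in enumerate(mask):
            if m:
                cur = (cur[0], i) if cur else (i, i)
                if cur[1] - cur[0] + 1 > best_len:
                    best, best_len = cur, cur[1] - cur[0] + 1
            else:
                cur = None
        lo, hi = pl.bin_edges[best[0]], pl.bin_edges[best[1] + 1]
    else:
        lo, hi = region
    centers = pl.centers
    inside = (centers >= lo) & (centers < hi)
    if not inside.any():
        raise ValueError("empty overlap region")
    widths = pl.widths
    masses = {
        k: float(np.sum(profiles[k].values[inside] * widths[inside]))
        for k in profiles
    }
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("no mass in the overlap region")
    return RelativeDensityResult(
        fractions={k: m / total for k, m in masses.items()}, region=(float(lo), float(hi))
    )


def hydration(
    system: SystemModel,
    frames: Frame | list[Frame],
    region: str = "CORE",
    bin_width: float = 0.1,
):
    """Core water density (g/cm³) or the water density profile along z.

    CORE: water mass between the two PL tail planes divided by that slab's
    volume, averaged over frames.  PROFILE: frame-averaged water mass
    density profile in g/cm³.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    waters = system.select(mclass=MoleculeClass.WATER)
    if region == "PROFILE":
        if len(waters) == 0:
            lz = frames[0].box[2]
            edges = np.arange(0.0, lz + bin_width, bin_width)
            return Profile(edges, np.zeros(len(edges) - 1), units="g/cm^3")
        prof = mass_density_profile(
            system, frames, mclass=MoleculeClass.WATER, bin_width=bin_width
        )
        return Profile(prof.bin_edges, prof.values / 1000.0, units="g/cm^3")
    if region != "CORE":
        raise ValueError("region must be CORE or PROFILE")
    dens = []
    for fr in frames:
        top = pl_tail_mean_z(system, fr, Leaflet.TOP)
        bottom = pl_tail_mean_z(system, fr, Leaflet.BOTTOM)
        if top <= bottom:
            raise ValueError("tail planes are inverted; check leaflet assignment")
        vol = fr.box[0] * fr.box[1] * (top - bottom)
        if len(waters) == 0:
            dens.append(0.0)
            continue
        z = fr.coords[waters, 2]
        m = float(np.sum(system.masses[waters][(z > bottom) & (z < top)]))
        dens.append(m / vol * AMU_PER_NM3 / 1000.0)
    return float(np.mean(dens))
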