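"""Synthetic trilayer configurations with known ground truth.

Generates pseudo-molecular systems that reproduce the statistical and
geometric structure the analysis operators measure — smectic layering with
tunable spacing and orientational order, alternating up/down sterol-ester
orientations, phospholipid monolayers at a prescribed area per lipid,
surface-oriented triacylglycerols, planted packing-defect patches, and core
hydration — without any molecular dynamics.  Every generated observable is
recoverable by the corresponding analyzer, which is the backbone of the
test suite.

Pseudo-molecules carry only the role-bearing atoms the analyzers consume
(ester oxygens, sterol ring/side-chain atoms, acyl carbons/hydrogens, head
groups); there is no bonded topology or energetics.  Orientation sampling
uses a Maier–Saupe-like axial distribution p(cosθ) ∝ exp(a cos²θ) with the
concentration a solved so the expected nematic order equals the target.
All randomness flows from the spec seed; the deterministic up/down mode
plants exact per-layer fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .core import (
    Frame,
    Leaflet,
    MoleculeClass,
    SystemModel,
    assign_leaflets,
    build_system,
    default_role_map,
)
from .dihedrals import DihedralScan
from .interdig import AMU_PER_NM3

__all__ = [
    "SyntheticSpec",
    "generate_core",
    "generate_trilayer",
    "generate_trilayer_trajectory",
    "generate_defect_leaflet",
    "sample_defect_sizes",
    "synthetic_pes",
    "solve_axial_concentration",
    "sample_axes",
    "trilayer_ground_truth",
]

WATER_MASS = 18.015  # single-site pseudo-water, g/mol


@dataclass
class SyntheticSpec:
    """Construction parameters of a synthetic trilayer.

    Defaults emulate the sterol-ester-rich (90:10 CHYO:TG) study system:
    242 neutral lipids over a ~9.15 nm box (APL 0.619 nm² for 135 PLs per
    leaflet), two smectic layers 3.45 nm apart at orientational order 0.81,
    equal up/down proportions, and a trace core hydration of 0.0025 g/cm³.
    """

    target_S: float = 0.81
    layer_spacing: float = 3.45  # nm
    n_layers: int = 2
    updown_ratio: float = 0.5
    n_chyo: int = 218
    n_tg: int = 24
    n_pl_per_leaflet: int = 135
    surf_tg_fraction: float = 0.0
    box: tuple[float, float, float] = (9.15, 9.15, 16.0)
    core_half_thickness: float = 4.0  # nm, tail plane offset from box centre
    planted_defects: list = field(default_factory=list)  # (leaflet, type, size Å², count)
    water_density_core: float = 0.0025  # g/cm³
    water_density_slab: float = 1.0  # g/cm³, cytosolic slabs
    deterministic_updown: bool = True
    position_jitter: float = 0.02  # nm, on ester-oxygen planes
    seed: int = 0

    def validate(self) -> None:
        if not -0.5 <= self.target_S <= 1.0:
            raise ValueError("target_S must lie in [-0.5, 1]")
        for frac in (self.updown_ratio, self.surf_tg_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.layer_spacing <= 0:
            raise ValueError("layer spacing must be positive")
        if self.n_layers < 1:
            raise ValueError("need at least one smectic layer")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        if self.n_layers >= 1 and (self.n_layers - 1) * self.layer_spacing >= self.box[2]:
            raise ValueError("layers do not fit in the box")
        if self.n_pl_per_leaflet > 0:
            apl = self.box[0] * self.box[1] / self.n_pl_per_leaflet
            if apl < 0.4:
                raise ValueError(f"infeasible area per lipid {apl:.3f} nm² (< 0.4)")


# ---------------------------------------------------------------------------
# Orientation sampling
# ---------------------------------------------------------------------------


def _expected_S(a: float) -> float:
    u = np.linspace(0.0, 1.0, 4001)
    w = np.exp(a * (u * u - 1.0))  # shifted for numerical stability
    p2 = 1.5 * u * u - 0.5
    return float(np.trapezoid(p2 * w, u) / np.trapezoid(w, u))


def solve_axial_concentration(target_S: float) -> float:
    """Concentration a of p(u) ∝ exp(a u²) with E[3/2 u² − 1/2] = target."""
    if not -0.5 < target_S < 1.0:
        raise ValueError("solvable only for S strictly inside (-0.5, 1)")
    lo, hi = -200.0, 500.0
    return float(brentq(lambda a: _expected_S(a) - target_S, lo, hi, xtol=1e-10))


def sample_axes(rng: np.random.Generator, n: int, target_S: float) -> np.ndarray:
    """Unit vectors in the upper hemisphere whose expected nematic order
    about +z equals ``target_S``; S = 1 and S = −0.5 are exact limits."""
    if n == 0:
        return np.zeros((0, 3))
    phi = rng.uniform(0.0, 2 * np.pi, n)
    if target_S >= 1.0 - 1e-12:
        return np.tile([0.0, 0.0, 1.0], (n, 1))
    if target_S <= -0.5 + 1e-12:
        return np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
    a = solve_axial_concentration(target_S)
    grid = np.linspace(0.0, 1.0, 4001)
    pdf = np.exp(a * (grid * grid - 1.0))
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2)])
    cdf /= cdf[-1]
    u = np.interp(rng.uniform(0.0, 1.0, n), cdf, grid)
    s = np.sqrt(np.maximum(0.0, 1.0 - u * u))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), u])


def _updown_flags(rng: np.random.Generator, n: int, ratio: float, deterministic: bool) -> np.ndarray:
    """True = up.  Deterministic mode interleaves exactly round(n·ratio) ups."""
    if deterministic:
        i = np.arange(n)
        return np.floor((i + 1) * ratio) - np.floor(i * ratio) >= 1
    return rng.random(n) < ratio


def _perp(d: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e = np.cross(d, ref)
    return e / np.linalg.norm(e)


# ---------------------------------------------------------------------------
# Pseudo-molecule builders.  Each returns (names, coords) lists.
# ---------------------------------------------------------------------------

# offsets (nm) of sterol atoms along the molecular axis; the lateral jitter
# pattern sums to zero and is uncorrelated with the axial offsets, so the
# gyration principal axis is exactly the construction axis.
_CHYO_AXIAL = np.array([0.25, 0.45, 0.65, 0.85, 1.05, 1.35])
_CHYO_LATERAL = np.array([0.04, -0.04, -0.04, 0.04, 0.0, 0.0])


def _build_chyo(p0: np.ndarray, d: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Sterol-ester pseudo-molecule: ester oxygens at p0, sterol body along
    +d, oleate tail along −d."""
    e = _perp(d)
    names = ["O1", "O2", "R1", "R2", "R3", "R4", "R5", "S1", "T1", "T2", "T3"]
    coords = [p0, p0 + 0.05 * d]
    for t, s in zip(_CHYO_AXIAL, _CHYO_LATERAL):
        coords.append(p0 + t * d + s * e)
    for t in (0.25, 0.5, 0.75):
        coords.append(p0 - t * d)
    return names, np.array(coords)


def _build_tg(rng: np.random.Generator, center: np.ndarray, tails_down: bool | None = None) -> tuple[list[str], np.ndarray]:
    """Triacylglycerol pseudo-molecule: six oxygens clustered at the centre,
    three 3-carbon tails.  ``tails_down`` forces tails toward −z (SURF
    geometry); None gives random tail directions."""
    names, coords = [], []
    ox_offsets = 0.05 * np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
    )
    for i, off in enumerate(ox_offsets):
        names.append(f"E{i + 1}" if i < 3 else f"G{i - 2}")
        coords.append(center + off)
    for tail in range(3):
        theta = rng.uniform(0, 2 * np.pi)
        if tails_down is None:
            zdir = rng.uniform(-1, 1)
        else:
            zdir = -0.9 if tails_down else 0.9
        d = np.array([np.cos(theta) * 0.4, np.sin(theta) * 0.4, zdir])
        d /= np.linalg.norm(d)
        for k in range(3):
            names.append(f"A{tail * 3 + k + 1}")
            coords.append(center + (0.2 + 0.15 * k) * d)
    return names, np.array(coords)


def _build_pl(site: np.ndarray, tail_plane: float, leaflet: Leaflet) -> tuple[list[str], np.ndarray]:
    """Phospholipid pseudo-molecule: phosphorus/head outward, four tail
    carbons symmetric about the tail plane (their mean z is the plane
    exactly), two in-plane hydrogens per carbon."""
    sign = 1.0 if leaflet is Leaflet.TOP else -1.0
    x, y = site
    names = ["P", "ND"]
    coords = [
        np.array([x, y, tail_plane + sign * 1.2]),
        np.array([x, y, tail_plane + sign * 1.35]),
    ]
    for k, dz in enumerate((0.45, 0.15, -0.15, -0.45)):
        cz = tail_plane + sign * dz
        names.append(f"C{k + 1}")
        coords.append(np.array([x, y, cz]))
        for tag, dx in (("A", 0.109), ("B", -0.109)):
            names.append(f"H{k + 1}{tag}")
            coords.append(np.array([x + dx, y, cz]))
    return names, np.array(coords)


def _grid_sites(n: int, lx: float, ly: float) -> np.ndarray:
    k = int(math.ceil(math.sqrt(n)))
    xs = (np.arange(k) + 0.5) * (lx / k)
    ys = (np.arange(k) + 0.5) * (ly / k)
    pts = np.array([(x, y) for y in ys for x in xs])
    return pts[:n]


class _Builder:
    """Accumulates pseudo-molecules and assembles the SystemModel."""

    def __init__(self) -> None:
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.coords: list[np.ndarray] = []
        self._resid = 0

    def add(self, resname: str, names: list[str], coords: np.ndarray) -> None:
        self._resid += 1
        self.names.extend(names)
        self.resnames.extend([resname] * len(names))
        self.resids.extend([self._resid] * len(names))
        self.coords.append(np.atleast_2d(coords))

    def finish(self, box, time: float = 0.0) -> tuple[SystemModel, Frame]:
        system = build_system(self.names, self.resnames, self.resids, default_role_map())
        xyz = np.concatenate(self.coords, axis=0)
        box = np.asarray(box, dtype=float)
        xyz[:, 0] = np.mod(xyz[:, 0], box[0])
        xyz[:, 1] = np.mod(xyz[:, 1], box[1])
        xyz[:, 2] = np.clip(xyz[:, 2], 0.0, np.nextafter(box[2], 0.0))
        return system, Frame(xyz, box, time)


def _place_core_lipids(
    b: _Builder, spec: SyntheticSpec, rng: np.random.Generator,
    z_lo: float, z_hi: float, n_core_tg: int, shallow_tg: bool = False,
) -> dict:
    """Smectic CHYO layers plus interspersed core TGs inside [z_lo, z_hi].

    Returns ground-truth bookkeeping (layer planes, per-layer up counts).
    """
    lx, ly, lz = spec.box
    zc = 0.5 * (z_lo + z_hi)
    planes = zc + (np.arange(spec.n_layers) - (spec.n_layers - 1) / 2) * spec.layer_spacing
    if spec.n_layers and (planes[0] < z_lo - 1e-9 or planes[-1] > z_hi + 1e-9):
        raise ValueError("smectic layers do not fit between the leaflets")
    per_layer = [spec.n_chyo // spec.n_layers] * spec.n_layers
    for i in range(spec.n_chyo - sum(per_layer)):
        per_layer[i % spec.n_layers] += 1

    truth_layers = []
    for li, (plane, n_l) in enumerate(zip(planes, per_layer)):
        axes = sample_axes(rng, n_l, spec.target_S)
        ups = _updown_flags(rng, n_l, spec.updown_ratio, spec.deterministic_updown)
        sites = _grid_sites(n_l, lx, ly)
        for j in range(n_l):
            d = axes[j] if ups[j] else -axes[j]
            jit = rng.normal(0.0, spec.position_jitter)
            p0 = np.array([sites[j, 0], sites[j, 1], plane + jit])
            names, coords = _build_chyo(p0, d)
            b.add("CHY", names, coords)
        truth_layers.append({"plane": float(plane), "n": n_l, "n_up": int(ups.sum())})

    margin = 0.45
    for k in range(n_core_tg):
        if shallow_tg and k % 2 == 0:
            # interdigitating TGs sit just below a tail plane
            plane = z_hi if k % 4 == 0 else z_lo
            zc_tg = plane - 0.5 if plane == z_hi else plane + 0.5
        else:
            zc_tg = rng.uniform(z_lo + margin, z_hi - margin)
        center = np.array([rng.uniform(0, lx), rng.uniform(0, ly), zc_tg])
        names, coords = _build_tg(rng, center)
        b.add("TGL", names, coords)
    return {"planes": planes.tolist(), "layers": truth_layers}


def _place_waters(
    b: _Builder, rng: np.random.Generator, lx: float, ly: float,
    z_lo: float, z_hi: float, density: float,
) -> int:
    """Uniform single-site waters in a slab at the given g/cm³; returns n."""
    vol = lx * ly * (z_hi - z_lo)
    if vol <= 0 or density <= 0:
        return 0
    n = int(round(density * 1000.0 / AMU_PER_NM3 * vol / WATER_MASS))
    for _ in range(n):
        pos = np.array([rng.uniform(0, lx), rng.uniform(0, ly), rng.uniform(z_lo, z_hi)])
        b.add("SOL", ["W1"], pos)
    return n


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def generate_core(spec: SyntheticSpec) -> tuple[SystemModel, Frame]:
    """Neutral-lipid core only: smectic CHYO layers + interspersed TGs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    b = _Builder()
    _place_core_lipids(b, spec, rng, 0.0, spec.box[2], spec.n_tg)
    return b.finish(spec.box)


def trilayer_ground_truth(spec: SyntheticSpec) -> dict:
    """Planted observables implied by a spec (deterministic bookkeeping)."""
    lx, ly, lz = spec.box
    zc = lz / 2
    top_plane = zc + spec.core_half_thickness
    bottom_plane = zc - spec.core_half_thickness
    core_vol = lx * ly * (top_plane - bottom_plane)
    n_core_w = int(round(
        spec.water_density_core * 1000.0 / AMU_PER_NM3 * core_vol / WATER_MASS
    ))
    n_surf = int(round(spec.surf_tg_fraction * spec.n_tg))
    return {
        "apl": lx * ly / spec.n_pl_per_leaflet,
        "tail_plane_top": top_plane,
        "tail_plane_bottom": bottom_plane,
        "n_surf_tg": n_surf,
        "surf_fraction_top": n_surf / (spec.n_pl_per_leaflet + n_surf),
        "core_water_density": n_core_w * WATER_MASS * AMU_PER_NM3 / core_vol / 1000.0,
        "n_core_waters": n_core_w,
        "layer_spacing": spec.layer_spacing,
        "updown_ratio": spec.updown_ratio,
        "target_S": spec.target_S,
    }


def generate_trilayer(spec: SyntheticSpec) -> tuple[SystemModel, Frame]:
    """Full trilayer: two PL monolayers, neutral-lipid core, water slabs.

    Head groups point outward; the planted area per lipid is
    Lx·Ly/n_pl_per_leaflet; round(surf_tg_fraction·n_tg) TGs are placed with
    all six oxygens above the top tail plane (SURF geometry); optional core
    water at ``water_density_core``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = trilayer_ground_truth(spec)
    lx, ly, lz = spec.box
    top_plane = truth["tail_plane_top"]
    bottom_plane = truth["tail_plane_bottom"]

    b = _Builder()
    for leaflet, plane in ((Leaflet.TOP, top_plane), (Leaflet.BOTTOM, bottom_plane)):
        for site in _grid_sites(spec.n_pl_per_leaflet, lx, ly):
            names, coords = _build_pl(site, plane, leaflet)
            b.add("PLM", names, coords)

    n_surf = truth["n_surf_tg"]
    for _ in range(n_surf):
        center = np.array([
            rng.uniform(0, lx), rng.uniform(0, ly), top_plane + 0.35,
        ])
        names, coords = _build_tg(rng, center, tails_down=True)
        b.add("TGL", names, coords)

    core_truth = _place_core_lipids(
        b, spec, rng, bottom_plane, top_plane, spec.n_tg - n_surf, shallow_tg=True
    )
    _place_waters(b, rng, lx, ly, bottom_plane, top_plane, spec.water_density_core)
    head_top = top_plane + 1.45
    head_bot = bottom_plane - 1.45
    _place_waters(b, rng, lx, ly, head_top + 0.3, lz, spec.water_density_slab)
    _place_waters(b, rng, lx, ly, 0.0, head_bot - 0.3, spec.water_density_slab)

    system, frame = b.finish(spec.box)
    system = assign_leaflets(system, frame)
    return system, frame


def generate_trilayer_trajectory(
    spec: SyntheticSpec,
    n_frames: int = 10,
    dt: float = 1.0,
    area_amplitude: float = 0.04,
    penetration_scale: float = 4.0,
    jitter: float = 0.005,
) -> tuple[SystemModel, list[Frame]]:
    """Trajectory with correlated area-per-lipid and interdigitation drive.

    A smooth modulation f_t = 1 + area_amplitude·sin(2πt/n) scales the box
    area (hence APL) while the interdigitating core TGs shift toward the
    tail planes by penetration_scale·(f_t − 1) nm, producing a positive
    APL–λ_ov correlation like the one the ordered-core system shows.
    Composition and topology are constant across frames.
    """
    system, base = generate_trilayer(spec)
    rng = np.random.default_rng(spec.seed + 1)
    zc = spec.box[2] / 2
    tg_mols = system.molecules_of_class(MoleculeClass.TG)
    frames = []
    for j in range(n_frames):
        f = 1.0 + area_amplitude * math.sin(2 * math.pi * j / n_frames)
        coords = base.coords.copy()
        coords[:, :2] *= math.sqrt(f)
        delta = penetration_scale * (f - 1.0)
        for m in tg_mols:
            idx = system.molecules[m]
            mz = coords[idx, 2].mean()
            if abs(mz - zc) > 0.5 * spec.core_half_thickness:
                coords[idx, 2] += delta if mz > zc else -delta
        coords += rng.normal(0.0, jitter, coords.shape)
        box = np.array([base.box[0] * math.sqrt(f), base.box[1] * math.sqrt(f), base.box[2]])
        coords[:, 0] = np.mod(coords[:, 0], box[0])
        coords[:, 1] = np.mod(coords[:, 1], box[1])
        coords[:, 2] = np.clip(coords[:, 2], 0.0, np.nextafter(box[2], 0.0))
        frames.append(Frame(coords, box, time=j * dt))
    return system, frames


# -- defect leaflets --------------------------------------------------------

_PATCH_BUILDERS = {
    "PL_ACYL": ("PAD", "A"),
    "TG_ACYL": ("TAD", "A"),
    "TG_GLYC": ("TGD", "O"),
    "CHYO_ACYL": ("CAD", "A"),
    "CHYO_SIDE": ("CSD", "R"),
}


def _patch_cells(size: int) -> np.ndarray:
    """``size`` connected cells filling a near-square bounding box
    column-major (the last column may be partial); 4-connected by design."""
    ph = int(math.isqrt(size))
    pw = math.ceil(size / ph)
    cells = [(i, j) for i in range(pw) for j in range(ph)]
    return np.array(cells[:size])


def generate_defect_leaflet(
    spec: SyntheticSpec,
) -> tuple[SystemModel, Frame, list[tuple[str, int]]]:
    """A single leaflet tiled by head-group markers except planted patches.

    Every 1 Å grid cell of the x–y box carries a head marker at z = 2.5 nm,
    except rectangular patches (from ``spec.planted_defects`` entries
    (leaflet, type, size Å², count)) filled with markers of the requested
    defect type at z = 2.6 nm.  Markers have 0.1 Å radii so each covers
    exactly its own cell; patches are placed with at least one clear cell
    between them.  Returns the exact expected cluster inventory.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lx, ly = spec.box[0], spec.box[1]
    w, h = int(round(lx * 10)), int(round(ly * 10))
    blocked = np.zeros((w, h), dtype=bool)  # patches plus their 1-cell margin
    patch_cells: list[tuple[str, np.ndarray]] = []
    truth: list[tuple[str, int]] = []

    wanted: list[tuple[str, int]] = []
    for leaflet, dtype, size, count in spec.planted_defects:
        if dtype not in _PATCH_BUILDERS:
            raise ValueError(f"unknown defect type {dtype!r}")
        wanted += [(dtype, int(size))] * int(count)
    # place the largest patches first: greedy rejection sampling stays
    # feasible at much higher packing fractions that way
    wanted.sort(key=lambda e: e[1], reverse=True)

    for dtype, size in wanted:
        base = _patch_cells(size)
        pw, ph = int(base[:, 0].max()) + 1, int(base[:, 1].max()) + 1
        if pw + 2 > w or ph + 2 > h:
            raise ValueError(f"patch of size {size} does not fit in the box")
        for _try in range(5000):
            x0 = int(rng.integers(1, w - pw))
            y0 = int(rng.integers(1, h - ph))
            if not blocked[x0 - 1 : x0 + pw + 1, y0 - 1 : y0 + ph + 1].any():
                break
        else:
            raise ValueError("cannot place planted patches without overlap")
        blocked[x0 - 1 : x0 + pw + 1, y0 - 1 : y0 + ph + 1] = True
        patch_cells.append((dtype, base + np.array([x0, y0])))
        truth.append((dtype, size))

    in_patch = np.zeros((w, h), dtype=bool)
    for _, cells in patch_cells:
        in_patch[cells[:, 0], cells[:, 1]] = True

    b = _Builder()
    z_head, z_mark, z_park = 2.5, 2.6, 0.2
    cc = 0.05  # cell centre offset, nm (0.5 Å)
    for i in range(w):
        for j in range(h):
            if not in_patch[i, j]:
                b.add("HDP", ["P"], np.array([i / 10 + cc, j / 10 + cc, z_head]))

    for dtype, cells in patch_cells:
        resname, prefix = _PATCH_BUILDERS[dtype]
        pts = cells / 10.0 + cc
        if dtype == "TG_GLYC":
            # six oxygens per TG molecule, distributed over the patch cells;
            # surplus oxygens stack on already-covered cells slightly lower.
            n_mol = math.ceil(len(cells) / 6)
            slots = [pts[k % len(pts)] for k in range(n_mol * 6)]
            for mi in range(n_mol):
                names, coords = [], []
                for oi in range(6):
                    k = mi * 6 + oi
                    zz = z_mark if k < len(pts) else z_mark - 0.01
                    names.append(f"O{oi + 1}")
                    coords.append(np.array([slots[k][0], slots[k][1], zz]))
                b.add(resname, names, np.array(coords))
        else:
            names, coords = [], []
            anchor = pts[0]
            if dtype in ("TG_ACYL",):
                for oi in range(6):
                    names.append(f"O{oi + 1}")
                    coords.append(np.array([anchor[0], anchor[1], z_park - 0.01 * oi]))
            elif dtype in ("CHYO_ACYL", "CHYO_SIDE"):
                for oi in range(2):
                    names.append(f"O{oi + 1}")
                    coords.append(np.array([anchor[0], anchor[1], z_park - 0.01 * oi]))
            for k, p in enumerate(pts):
                names.append(f"{prefix}{k + 1}")
                coords.append(np.array([p[0], p[1], z_mark]))
            b.add(resname, names, np.array(coords))

    system, frame = b.finish(spec.box)
    for m in system.molecules_of_class(MoleculeClass.PL):
        system.leaflets[m] = Leaflet.TOP
    return system, frame, truth


def sample_defect_sizes(pi_true: float, n: int, seed: int) -> np.ndarray:
    """Integer sizes from the discretized exponential law P(N) ∝ e^(−N/π),
    N ≥ 1 (a geometric distribution with q = e^(−1/π))."""
    if pi_true <= 0:
        raise ValueError("pi_true must be positive")
    if n == 0:
        return np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    p = 1.0 - math.exp(-1.0 / pi_true)
    return rng.geometric(p, size=n)


def synthetic_pes(
    k_true: list[tuple[int, float, float]],
    phi_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DihedralScan:
    """Synthetic dihedral scan E(φ) = Σ k(1 + cos(nφ − δ)) + Gaussian noise."""
    phi = np.asarray(phi_grid, dtype=float)
    phi_r = np.deg2rad(phi)
    e = np.zeros_like(phi_r)
    for n, k, delta in k_true:
        e += k * (1.0 + np.cos(n * phi_r - np.deg2rad(delta)))
    if noise_sd > 0:
        e = e + np.random.default_rng(seed).normal(0.0, noise_sd, e.shape)
    return DihedralScan(phi, e)
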