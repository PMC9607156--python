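"""Cartesian-grid packing defect analysis.

Atoms of a leaflet above a depth threshold (mean leaflet phosphorus z minus
2 nm) are projected onto a 1 Å x–y grid.  A grid cell is covered by an atom
when the in-plane distance from the cell centre to the atom is smaller than
the atom's vdW radius plus a half-diagonal constant (default √3/2 Å,
following the printed convention; √2/2 is the planar half-diagonal and is
available as an option).  Cells covered by polar PL head groups are not
defects; cells whose outermost covering atom is an acyl/neutral-lipid atom
are elementary defects typed by that atom (PL-acyl, TG-acyl, TG-glycerol,
CHYO-acyl, CHYO-side).  Neighbouring elementary defects are clustered
(4-connected by default, periodic in x–y); a cluster of N cells has size
N Å².  The size distribution P(N) is fit to c·exp(−N/π), where π is the
packing defect constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    Frame,
    Leaflet,
    LIPID_CLASSES,
    MoleculeClass,
    Role,
    SystemModel,
)

__all__ = [
    "CELL_TYPES",
    "DEFECT_TYPES",
    "DefectGrid",
    "DefectCluster",
    "DefectFit",
    "build_defect_grid",
    "label_grid",
    "cluster_defects",
    "collect_cluster_sizes",
    "size_distribution",
    "fit_defect_constant",
    "prob_ge",
    "prob_ge_ratio",
]

CELL_TYPES = [
    "UNCOVERED",
    "HEAD",
    "PL_ACYL",
    "TG_ACYL",
    "TG_GLYC",
    "CHYO_ACYL",
    "CHYO_SIDE",
]
CELL_CODE = {name: i for i, name in enumerate(CELL_TYPES)}
DEFECT_TYPES = ["PL_ACYL", "TG_ACYL", "TG_GLYC", "CHYO_ACYL", "CHYO_SIDE"]

HALF_DIAGONAL_PRINTED = math.sqrt(3.0) / 2.0  # Å, printed convention
HALF_DIAGONAL_PLANAR = math.sqrt(2.0) / 2.0  # Å, geometric 2-D half-diagonal


@dataclass
class DefectGrid:
    leaflet: Leaflet
    spacing: float  # Å (nominal)
    cell_size: tuple[float, float]  # Å, actual after fitting the box
    types: np.ndarray  # (nx, ny) int codes into CELL_TYPES
    top_z: np.ndarray  # (nx, ny) outermost covering-atom z (Å), nan if uncovered
    top_atom: np.ndarray  # (nx, ny) atom index, -1 if uncovered
    z_thr: float  # Å

    @property
    def cell_area(self) -> float:
        return self.cell_size[0] * self.cell_size[1]

    def defect_mask(self, defect_type: str | None = None, include_uncovered: bool = True) -> np.ndarray:
        """Boolean mask of elementary defect cells.

        With a ``defect_type``, only that species' cells; otherwise the
        overall mask (any defect type, plus UNCOVERED cells when
        ``include_uncovered``).
        """
        if defect_type is not None:
            if defect_type not in DEFECT_TYPES:
                raise ValueError(f"unknown defect type {defect_type!r}")
            return self.types == CELL_CODE[defect_type]
        mask = np.isin(self.types, [CELL_CODE[t] for t in DEFECT_TYPES])
        if include_uncovered:
            mask |= self.types == CELL_CODE["UNCOVERED"]
        return mask


@dataclass
class DefectCluster:
    defect_type: str
    cells: np.ndarray  # (n, 2) cell indices
    size: float  # Å²


@dataclass
class DefectFit:
    pi: float  # Å²
    c: float
    pi_se: float
    c_se: float
    fit_range: tuple[float, float]
    r_squared: float
    prob_ge_50: float | None = None


def _atom_cell_type(system: SystemModel, i: int) -> int:
    mc = system.mol_class_codes[i]
    r = int(system.roles[i])
    if mc is MoleculeClass.PL:
        if r & int(Role.HEAD | Role.PHOSPHORUS):
            return CELL_CODE["HEAD"]
        return CELL_CODE["PL_ACYL"]
    if mc is MoleculeClass.TG:
        if r & int(Role.ESTER_O | Role.GLYCEROL_O):
            return CELL_CODE["TG_GLYC"]
        return CELL_CODE["TG_ACYL"]
    if mc is MoleculeClass.CHYO:
        if r & int(Role.STEROL_RING | Role.STEROL_SIDE):
            return CELL_CODE["CHYO_SIDE"]
        return CELL_CODE["CHYO_ACYL"]
    raise ValueError("only lipid atoms can cover defect-grid cells")


def build_defect_grid(
    system: SystemModel,
    frame: Frame,
    leaflet: Leaflet,
    spacing: float = 1.0,
    half_diagonal: float = HALF_DIAGONAL_PRINTED,
    depth: float = 20.0,
) -> DefectGrid:
    """Project a leaflet's lipid atoms onto the packing-defect grid.

    ``spacing``/``half_diagonal``/``depth`` are in Å (depth is how far below
    the leaflet's mean phosphorus plane atoms are still candidates).  The
    grid spans the full periodic x–y box.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    mols = [
        m for m in system.molecules_of_class(MoleculeClass.PL)
        if system.leaflets.get(m) is leaflet
    ]
    if not mols:
        raise ValueError(f"no PL molecules on leaflet {leaflet.value}")
    p_atoms = system.select(roles=Role.PHOSPHORUS, molecules=mols)
    if len(p_atoms) == 0:
        raise ValueError("no phosphorus atoms on the leaflet")

    coords = frame.coords * 10.0  # nm -> Å
    box = frame.box * 10.0
    p_mean = float(np.mean(coords[p_atoms, 2]))
    sign = 1.0 if leaflet is Leaflet.TOP else -1.0
    z_thr = p_mean - sign * depth

    lipid_atoms = system.select(mclass=LIPID_CLASSES)
    z = coords[lipid_atoms, 2]
    cand = lipid_atoms[(z - z_thr) * sign > 0]  # strictly beyond the threshold

    nx = max(int(round(box[0] / spacing)), 1)
    ny = max(int(round(box[1] / spacing)), 1)
    cx, cy = box[0] / nx, box[1] / ny

    types = np.full((nx, ny), CELL_CODE["UNCOVERED"], dtype=np.int8)
    top_z = np.full((nx, ny), np.nan)
    top_atom = np.full((nx, ny), -1, dtype=int)
    head_cover = np.zeros((nx, ny), dtype=bool)
    best = np.full((nx, ny), -np.inf)  # sign * z of outermost covering atom

    for a in cand:
        x, y, az = coords[a]
        reach = system.radii[a] + half_diagonal
        ix0 = int(np.floor((x - reach) / cx - 0.5))
        ix1 = int(np.ceil((x + reach) / cx - 0.5))
        iy0 = int(np.floor((y - reach) / cy - 0.5))
        iy1 = int(np.ceil((y + reach) / cy - 0.5))
        ixs = np.arange(ix0, ix1 + 1)
        iys = np.arange(iy0, iy1 + 1)
        dx = (ixs + 0.5) * cx - x
        dx -= box[0] * np.round(dx / box[0])
        dy = (iys + 0.5) * cy - y
        dy -= box[1] * np.round(dy / box[1])
        d2 = dx[:, None] ** 2 + dy[None, :] ** 2
        hit = d2 < reach * reach
        if not hit.any():
            continue
        code = _atom_cell_type(system, a)
        gx = np.mod(ixs, nx)
        gy = np.mod(iys, ny)
        hx, hy = np.nonzero(hit)
        cells = (gx[hx], gy[hy])
        if code == CELL_CODE["HEAD"]:
            head_cover[cells] = True
        depth_metric = sign * az
        upd = depth_metric > best[cells]
        ux, uy = cells[0][upd], cells[1][upd]
        best[ux, uy] = depth_metric
        top_z[ux, uy] = az
        top_atom[ux, uy] = a
        types[ux, uy] = code

    types[head_cover] = CELL_CODE["HEAD"]
    return DefectGrid(
        leaflet=leaflet,
        spacing=spacing,
        cell_size=(cx, cy),
        types=types,
        top_z=top_z,
        top_atom=top_atom,
        z_thr=z_thr,
    )


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def label_grid(
    mask: np.ndarray, connectivity: int = 4, periodic: bool = True
) -> tuple[np.ndarray, int]:
    """Connected components of a boolean grid, periodic in both directions.

    Returns (labels, n) with labels in 1..n (0 = background), matching a
    flood fill with 4- or 8-neighbourhoods.
    """
    if connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    elif connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask, structure=structure)
    if not periodic or n == 0:
        return labels, n
    uf = _UnionFind(n + 1)
    nx, ny = mask.shape

    def _join(la: np.ndarray, lb: np.ndarray) -> None:
        for a, b in zip(la, lb):
            if a and b:
                uf.union(int(a), int(b))

    if nx > 1:
        _join(labels[0, :], labels[-1, :])
        if connectivity == 8 and ny > 1:
            _join(labels[0, :], np.roll(labels[-1, :], 1))
            _join(labels[0, :], np.roll(labels[-1, :], -1))
    if ny > 1:
        _join(labels[:, 0], labels[:, -1])
        if connectivity == 8 and nx > 1:
            _join(labels[:, 0], np.roll(labels[:, -1], 1))
            _join(labels[:, 0], np.roll(labels[:, -1], -1))
    if connectivity == 8 and nx > 1 and ny > 1:
        for ca, cb in (
            (labels[0, 0], labels[-1, -1]),
            (labels[0, -1], labels[-1, 0]),
        ):
            if ca and cb:
                uf.union(int(ca), int(cb))
    remap = np.zeros(n + 1, dtype=labels.dtype)
    roots: dict[int, int] = {}
    for lab in range(1, n + 1):
        r = uf.find(lab)
        if r not in roots:
            roots[r] = len(roots) + 1
        remap[lab] = roots[r]
    return remap[labels], len(roots)


def cluster_defects(
    grid: DefectGrid,
    connectivity: int = 4,
    per_type: bool = True,
    include_uncovered: bool = True,
) -> list[DefectCluster]:
    """Cluster neighbouring elementary defects.

    ``per_type=True`` clusters each defect species separately for the
    per-type statistics; ``per_type=False`` clusters all defect cells jointly
    for the overall defect probability, with UNCOVERED cells included when
    requested.
    """
    out: list[DefectCluster] = []
    if per_type:
        groups = [(t, grid.defect_mask(t)) for t in DEFECT_TYPES]
    else:
        groups = [("ANY", grid.defect_mask(include_uncovered=include_uncovered))]
    for name, mask in groups:
        labels, n = label_grid(mask, connectivity=connectivity, periodic=True)
        for lab in range(1, n + 1):
            cells = np.argwhere(labels == lab)
            out.append(
                DefectCluster(
                    defect_type=name,
                    cells=cells,
                    size=len(cells) * grid.cell_area,
                )
            )
    return out


def collect_cluster_sizes(
    system: SystemModel,
    frames: list[Frame],
    leaflets: tuple[Leaflet, ...] = (Leaflet.TOP, Leaflet.BOTTOM),
    per_type: bool = True,
    connectivity: int = 4,
    **grid_kwargs,
) -> dict[str, list[float]]:
    """Pool cluster sizes over frames and leaflets, keyed by defect type
    (or 'ANY' when ``per_type=False``)."""
    sizes: dict[str, list[float]] = {}
    for fr in frames:
        for lf in leaflets:
            grid = build_defect_grid(system, fr, lf, **grid_kwargs)
            for cl in cluster_defects(grid, connectivity=connectivity, per_type=per_type):
                sizes.setdefault(cl.defect_type, []).append(cl.size)
    return sizes


def size_distribution(sizes) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of cluster sizes: (N values, P(N))."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("no clusters")
    values, counts = np.unique(sizes, return_counts=True)
    return values, counts / counts.sum()


def fit_defect_constant(
    sizes,
    fit_range: tuple[float, float] | str = "AUTO",
    weighted: bool = True,
    min_count: int = 10,
    threshold: float = 50.0,
) -> DefectFit:
    """Fit ln P(N) = ln c − N/π over the chosen size range.

    AUTO range: [15 Å², largest N observed at least ``min_count`` times]
    (small sizes deviate from the exponential tail).  The fit is weighted
    by bin counts by default.  ``prob_ge_50`` is the empirical fraction of
    clusters at or above ``threshold``, not a fit extrapolation.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("no clusters")
    values, counts = np.unique(sizes, return_counts=True)
    probs = counts / counts.sum()
    if len(values) < 2:
        raise ValueError("degenerate (single-size) distribution")
    if isinstance(fit_range, str):
        if fit_range != "AUTO":
            raise ValueError("fit_range must be (N_min, N_max) or 'AUTO'")
        eligible = values[counts >= min_count]
        n_min = 15.0
        n_max = float(eligible.max()) if eligible.size else float(values.max())
        if n_max <= n_min:
            n_min, n_max = float(values.min()), float(values.max())
    else:
        n_min, n_max = fit_range
    sel = (values >= n_min) & (values <= n_max) & (probs > 0)
    if sel.sum() < 3:
        raise ValueError("need at least 3 nonzero bins in the fit range")
    x = values[sel]
    y = np.log(probs[sel])
    w = counts[sel].astype(float) if weighted else np.ones(sel.sum())

    # weighted linear least squares: y = b0 + b1 x, pi = -1/b1
    sw = np.sqrt(w)
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    resid = y - design @ coef
    dof = len(x) - 2
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(design.T @ (design * w[:, None]))
    b0, b1 = coef
    if b1 >= 0:
        raise ValueError("non-decaying size distribution; cannot fit a defect constant")
    pi = -1.0 / b1
    pi_se = float(np.sqrt(cov[1, 1])) * pi * pi  # delta method: d(−1/b1)/db1 = 1/b1²
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - float(np.sum(w * resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return DefectFit(
        pi=float(pi),
        c=float(np.exp(b0)),
        pi_se=pi_se,
        c_se=float(np.sqrt(cov[0, 0]) * np.exp(b0)),
        fit_range=(float(n_min), float(n_max)),
        r_squared=r2,
        prob_ge_50=prob_ge(sizes, threshold),
    )


def prob_ge(sizes, threshold: float = 50.0) -> float:
    """Empirical probability that a defect cluster has size ≥ threshold Å²."""
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("empty input")
    return float(np.mean(sizes >= threshold))


def prob_ge_ratio(sizes_a, sizes_b, threshold: float = 50.0) -> float:
    """How many times more likely system A exhibits defects ≥ threshold."""
    pb = prob_ge(sizes_b, threshold)
    if pb == 0:
        raise ValueError("reference system has no defects at or above the threshold")
    return prob_ge(sizes_a, threshold) / pb
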