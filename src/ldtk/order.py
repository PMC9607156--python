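"""Liquid-crystal ordering analysis.

Nematic (orientational) order parameter S = <3/2 cos²θ − 1/2> of the sterol
ester long axes against the system director, per-carbon acyl tail order
parameters S_CD, 3-D and in-plane 2-D radial distribution functions of
sterol centres of mass, smectic layer spacing from the ester-oxygen density
profile, and up/down orientation fractions per smectic layer.

The director is by default the eigenvector of the largest eigenvalue of the
Q-tensor Q = <(3/2) v v^T − (1/2) I> (rotation-invariant); a fixed axis can
be supplied instead, in which case S is signed relative to that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import (
    Frame,
    MoleculeClass,
    Role,
    SystemModel,
    minimum_image,
)

__all__ = [
    "Profile",
    "OrientationSet",
    "OrderResult",
    "molecular_axis",
    "molecular_axes",
    "nematic_order",
    "tail_order",
    "rdf3d",
    "rdf2d",
    "number_density_profile",
    "layer_spacing",
    "assign_layers",
    "updown_fractions",
]


@dataclass
class Profile:
    """A binned one-dimensional function of z."""

    bin_edges: np.ndarray  # nm, length n+1
    values: np.ndarray  # length n
    units: str = ""
    axis: str = "z"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.bin_edges) - 1:
            raise ValueError("values must have one fewer entry than bin_edges")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)


@dataclass
class OrientationSet:
    """Oriented molecular long-axis unit vectors, one (n, 3) array per frame."""

    vectors: list[np.ndarray]
    director: np.ndarray | None = None
    axis_definition: str = "gyration-tensor principal axis of sterol heavy atoms"
    molecule_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.vectors = [np.atleast_2d(np.asarray(v, dtype=float)) for v in self.vectors]

    @property
    def all_vectors(self) -> np.ndarray:
        return np.concatenate(self.vectors, axis=0)


@dataclass
class OrderResult:
    S: float
    per_frame_S: np.ndarray
    director: np.ndarray
    converged_mean: float
    converged_sd: float
    window: tuple[int, int]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def molecular_axis(system: SystemModel, frame: Frame, molecule: int) -> np.ndarray:
    """Oriented long axis of one sterol-ester molecule.

    First principal axis of the gyration tensor of the sterol ring and
    side-chain atoms, with its sign fixed to point from the ester-oxygen end
    toward the side-chain end.
    """
    idx = system.molecules[molecule]
    roles = system.roles[idx]
    sterol = idx[(roles & int(Role.STEROL_RING | Role.STEROL_SIDE)) != 0]
    if np.sum((roles & int(Role.STEROL_RING)) != 0) < 3:
        raise ValueError(f"molecule {molecule}: need at least 3 sterol ring atoms")
    pos = frame.coords[sterol]
    centered = pos - pos.mean(axis=0)
    if np.allclose(centered, 0):
        raise ValueError(f"molecule {molecule}: colocated sterol atoms")
    gyr = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(gyr)
    axis = evecs[:, -1]
    ester = idx[(roles & int(Role.ESTER_O)) != 0]
    side = idx[(roles & int(Role.STEROL_SIDE)) != 0]
    if len(ester) and len(side):
        ref = frame.coords[side].mean(axis=0) - frame.coords[ester].mean(axis=0)
        if np.dot(axis, ref) < 0:
            axis = -axis
    return _unit(axis)


def molecular_axes(
    system: SystemModel,
    frames: Frame | list[Frame],
    mclass: MoleculeClass = MoleculeClass.CHYO,
) -> OrientationSet:
    """Oriented axes of every molecule of ``mclass`` for each frame."""
    if isinstance(frames, Frame):
        frames = [frames]
    mols = system.molecules_of_class(mclass)
    if not mols:
        raise ValueError(f"no molecules of class {mclass.value}")
    vecs = [
        np.array([molecular_axis(system, fr, m) for m in mols]) for fr in frames
    ]
    return OrientationSet(vectors=vecs, molecule_ids=mols)


def nematic_order(
    vectors: OrientationSet | np.ndarray | list[np.ndarray],
    director: np.ndarray | str = "auto",
    window_fraction: float = 0.5,
) -> OrderResult:
    """Orientational order parameter S = <3/2 cos²θ − 1/2>.

    θ is the angle between each molecular axis and the director; the
    ensemble average runs over molecules and frames.  ``director='auto'``
    uses the top eigenvector of the Q-tensor pooled over all frames; a
    fixed unit vector yields signed S relative to that axis.

    ``converged_mean``/``converged_sd`` summarize per-frame S over the last
    ``window_fraction`` of the frames.
    """
    if isinstance(vectors, OrientationSet):
        per_frame = vectors.vectors
    elif isinstance(vectors, list):
        per_frame = [np.atleast_2d(np.asarray(v, float)) for v in vectors]
    else:
        per_frame = [np.atleast_2d(np.asarray(vectors, float))]
    allv = np.concatenate(per_frame, axis=0)
    if allv.size == 0:
        raise ValueError("empty orientation set")
    norms = np.linalg.norm(allv, axis=1)
    if np.any(norms == 0):
        raise ValueError("orientation vectors must be nonzero")
    allv = allv / norms[:, None]

    if isinstance(director, str):
        if director != "auto":
            raise ValueError("director must be a vector or 'auto'")
        q = 1.5 * np.einsum("ni,nj->ij", allv, allv) / len(allv) - 0.5 * np.eye(3)
        evals, evecs = np.linalg.eigh(q)
        d = evecs[:, -1]
    else:
        d = _unit(np.asarray(director, dtype=float))

    def s_of(block: np.ndarray) -> float:
        b = block / np.linalg.norm(block, axis=1)[:, None]
        c = b @ d
        return float(np.mean(1.5 * c * c - 0.5))

    per_frame_S = np.array([s_of(v) for v in per_frame])
    S = s_of(allv)
    n = len(per_frame_S)
    lo = min(int(round(n * (1 - window_fraction))), n - 1)
    win = per_frame_S[lo:]
    return OrderResult(
        S=S,
        per_frame_S=per_frame_S,
        director=d,
        converged_mean=float(np.mean(win)),
        converged_sd=float(np.std(win, ddof=1)) if len(win) > 1 else 0.0,
        window=(lo, n),
    )


def tail_order(
    system: SystemModel,
    frames: Frame | list[Frame],
    lipid_class: MoleculeClass = MoleculeClass.PL,
    h_cutoff: float = 0.15,
) -> np.ndarray:
    """Per-carbon acyl order parameter S_CD(k).

    For carbon position k (order of acyl carbons within each molecule),
    S_CD = <3/2 cos²θ − 1/2> with θ the angle between each C–H bond vector
    and the +z membrane normal, averaged over hydrogens, molecules and
    frames.  Hydrogens are paired to their nearest acyl carbon within the
    molecule (must lie within ``h_cutoff`` nm).
    """
    if isinstance(frames, Frame):
        frames = [frames]
    mols = system.molecules_of_class(lipid_class)
    if not mols:
        raise ValueError(f"no molecules of class {lipid_class.value}")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for fr in frames:
        for m in mols:
            idx = system.molecules[m]
            roles = system.roles[idx]
            carbons = idx[(roles & int(Role.ACYL_C)) != 0]
            hydros = idx[(roles & int(Role.ACYL_H)) != 0]
            if len(carbons) == 0:
                continue
            cpos = fr.coords[carbons]
            seen = np.zeros(len(carbons), dtype=bool)
            for h in hydros:
                d = cpos - fr.coords[h]
                dist = np.linalg.norm(d, axis=1)
                k = int(np.argmin(dist))
                if dist[k] > h_cutoff:
                    continue
                seen[k] = True
                ch = fr.coords[h] - cpos[k]
                c = ch[2] / np.linalg.norm(ch)
                sums[k] = sums.get(k, 0.0) + (1.5 * c * c - 0.5)
                counts[k] = counts.get(k, 0) + 1
            if len(hydros) and not seen.all():
                missing = int(np.flatnonzero(~seen)[0])
                raise ValueError(
                    f"molecule {m}: acyl carbon position {missing} has no "
                    "paired hydrogen"
                )
    if not counts:
        raise ValueError("no C–H pairs found")
    kmax = max(counts) + 1
    out = np.full(kmax, np.nan)
    for k in counts:
        out[k] = sums[k] / counts[k]
    return out


def _com(
    system: SystemModel, frame: Frame, mols: list[int], roles: Role | None
) -> np.ndarray:
    """Mass-weighted centre of mass of selected roles per molecule."""
    coms = []
    for m in mols:
        idx = system.molecules[m]
        if roles is not None:
            idx = idx[(system.roles[idx] & int(roles)) != 0]
        if len(idx) == 0:
            raise ValueError(f"molecule {m}: no atoms with requested roles")
        w = system.masses[idx]
        coms.append(np.average(frame.coords[idx], axis=0, weights=w))
    return np.array(coms)


def rdf3d(
    system: SystemModel,
    frames: Frame | list[Frame],
    mclass: MoleculeClass = MoleculeClass.CHYO,
    reference_roles: Role | None = Role.STEROL_RING | Role.STEROL_SIDE,
    r_max: float = 3.0,
    dr: float = 0.02,
) -> Profile:
    """3-D radial distribution function of molecular (sterol) centres of mass.

    Minimum-image pair distances, normalized by the ideal-gas expectation at
    the observed number density, so g(r) → 1 for homogeneous input.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    if r_max > min(frames[0].box) / 2:
        raise ValueError("r_max exceeds half the smallest box dimension")
    mols = system.molecules_of_class(mclass)
    if len(mols) < 2:
        raise ValueError("need at least 2 reference molecules")
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    expected = np.zeros(len(edges) - 1)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    for fr in frames:
        pos = _com(system, fr, mols, reference_roles)
        n = len(pos)
        d = pos[:, None, :] - pos[None, :, :]
        d = minimum_image(d.reshape(-1, 3), fr.box).reshape(n, n, 3)
        dist = np.linalg.norm(d, axis=-1)
        iu = np.triu_indices(n, k=1)
        counts += np.histogram(dist[iu], bins=edges)[0]
        vbox = float(np.prod(fr.box))
        expected += n * (n - 1) / 2 * shell_vol / vbox
    vals = np.divide(counts, expected, out=np.zeros_like(counts), where=expected > 0)
    return Profile(edges, vals, units="dimensionless", axis="r")


def rdf2d(
    system: SystemModel,
    frames: Frame | list[Frame],
    layer_assignment: np.ndarray,
    mclass: MoleculeClass = MoleculeClass.CHYO,
    reference_roles: Role | None = Role.STEROL_RING | Role.STEROL_SIDE,
    r_max: float = 3.0,
    dr: float = 0.02,
) -> Profile:
    """In-plane (x–y) RDF between molecules of the same smectic layer.

    Area-density normalized with minimum image in x and y.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    mols = system.molecules_of_class(mclass)
    layer_assignment = np.asarray(layer_assignment)
    if len(layer_assignment) != len(mols):
        raise ValueError("layer_assignment must cover every molecule of the class")
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    expected = np.zeros(len(edges) - 1)
    ann = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    total_pairs = 0
    for fr in frames:
        pos = _com(system, fr, mols, reference_roles)[:, :2]
        area = float(fr.box[0] * fr.box[1])
        for lab in np.unique(layer_assignment):
            p = pos[layer_assignment == lab]
            n = len(p)
            if n < 2:
                continue
            total_pairs += n * (n - 1) // 2
            d = p[:, None, :] - p[None, :, :]
            d = minimum_image(d.reshape(-1, 2), fr.box[:2]).reshape(n, n, 2)
            dist = np.linalg.norm(d, axis=-1)
            iu = np.triu_indices(n, k=1)
            counts += np.histogram(dist[iu], bins=edges)[0]
            expected += n * (n - 1) / 2 * ann / area
    if total_pairs == 0:
        raise ValueError("no same-layer pairs (every layer has fewer than 2 molecules)")
    vals = np.divide(counts, expected, out=np.zeros_like(counts), where=expected > 0)
    return Profile(edges, vals, units="dimensionless", axis="r_xy")


def number_density_profile(
    system: SystemModel,
    frames: Frame | list[Frame],
    roles: Role,
    mclass: MoleculeClass | None = MoleculeClass.CHYO,
    bin_width: float = 0.1,
) -> Profile:
    """Number density of role-tagged atoms along z (counts per nm³)."""
    if isinstance(frames, Frame):
        frames = [frames]
    sel = system.select(mclass=mclass, roles=roles)
    if len(sel) == 0:
        raise ValueError("empty selection")
    lz = frames[0].box[2]
    edges = np.arange(0.0, lz + bin_width, bin_width)
    vals = np.zeros(len(edges) - 1)
    for fr in frames:
        z = np.mod(fr.coords[sel, 2], fr.box[2])
        area = fr.box[0] * fr.box[1]
        vals += np.histogram(z, bins=edges)[0] / (area * bin_width)
    vals /= len(frames)
    return Profile(edges, vals, units="nm^-3")


def layer_spacing(
    profile: Profile, prominence_frac: float = 0.1
) -> tuple[float, float, np.ndarray]:
    """Smectic layer spacing from the ester-oxygen density profile.

    Peaks are local maxima with prominence above ``prominence_frac`` of the
    profile maximum; spacing is the mean of successive peak separations and
    its standard deviation.
    """
    vals = profile.values
    peaks, _ = find_peaks(vals, prominence=prominence_frac * float(vals.max()))
    positions = profile.centers[peaks]
    if len(positions) < 2:
        raise ValueError("fewer than 2 peaks in the density profile")
    diffs = np.diff(positions)
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    return float(np.mean(diffs)), sd, positions


def assign_layers(
    system: SystemModel,
    frame: Frame,
    peak_positions: np.ndarray,
    mclass: MoleculeClass = MoleculeClass.CHYO,
    roles: Role = Role.STEROL_RING | Role.STEROL_SIDE,
) -> np.ndarray:
    """Assign each molecule to the nearest density peak by sterol-COM z."""
    mols = system.molecules_of_class(mclass)
    coms = _com(system, frame, mols, roles)
    peaks = np.asarray(peak_positions, dtype=float)
    return np.argmin(np.abs(coms[:, 2:3] - peaks[None, :]), axis=1)


def updown_fractions(
    vectors: OrientationSet | np.ndarray,
    layer_assignment: np.ndarray,
    director: np.ndarray = np.array([0.0, 0.0, 1.0]),
) -> dict[int, tuple[float, float]]:
    """Per-layer (up, down) fractions from oriented molecular axes.

    "Up" means sign(v · director) > 0 using the oriented axis (before the
    v ≡ −v symmetrization of the order parameter); fractions sum to 1.
    """
    if isinstance(vectors, OrientationSet):
        v = vectors.vectors[0] if len(vectors.vectors) == 1 else vectors.all_vectors
    else:
        v = np.atleast_2d(np.asarray(vectors, float))
    layer_assignment = np.asarray(layer_assignment)
    if len(layer_assignment) != len(v):
        raise ValueError("layer assignment length mismatch")
    d = _unit(np.asarray(director, float))
    out: dict[int, tuple[float, float]] = {}
    for lab in np.unique(layer_assignment):
        sel = v[layer_assignment == lab]
        if len(sel) == 0:
            raise ValueError(f"empty layer {lab}")
        up = float(np.mean(sel @ d > 0))
        out[int(lab)] = (up, 1.0 - up)
    return out
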