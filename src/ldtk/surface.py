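"""SURF/CORE classification of neutral lipids and monolayer packing.

A triacylglycerol is surface-oriented (SURF-TG) in a frame when all six of
its ester/glycerol oxygens lie strictly above the mean z of the top
leaflet's phospholipid tail carbons (mirrored for the bottom leaflet); a
sterol ester is SURF-CHYO when both of its ester oxygens pass the same
test.  Short-lived SURF episodes (< 5 ns by default) are relabelled CORE,
since brief oxygen excursions return to the bulk.  The module also computes
monolayer composition, area per lipid (APL) and the APL–interdigitation
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    Frame,
    Leaflet,
    MoleculeClass,
    NEUTRAL_LIPID_CLASSES,
    Role,
    SystemModel,
)

__all__ = [
    "SurfLabelSeries",
    "AplSeries",
    "pl_tail_mean_z",
    "classify_frame",
    "classify",
    "residence_filter",
    "monolayer_composition",
    "apl",
    "pearson",
]

LEAFLET_CODE = {Leaflet.NONE: 0, Leaflet.TOP: 1, Leaflet.BOTTOM: 2}


@dataclass
class SurfLabelSeries:
    """Per-molecule, per-frame SURF/CORE labels for the neutral lipids."""

    molecule_ids: list[int]  # NL molecule indices into SystemModel.molecules
    classes: list[MoleculeClass]
    times: np.ndarray  # ns, one per frame
    surf: np.ndarray  # bool, (n_molecules, n_frames)
    leaflet_code: np.ndarray  # int8, (n_molecules, n_frames); 0 core, 1 top, 2 bottom

    def copy(self) -> "SurfLabelSeries":
        return SurfLabelSeries(
            list(self.molecule_ids), list(self.classes), self.times.copy(),
            self.surf.copy(), self.leaflet_code.copy(),
        )

    def surf_count(self, leaflet: Leaflet, mclass: MoleculeClass | None = None) -> np.ndarray:
        """Per-frame number of SURF molecules on a leaflet."""
        mask = self.surf & (self.leaflet_code == LEAFLET_CODE[leaflet])
        if mclass is not None:
            rows = np.array([c is mclass for c in self.classes])
            mask = mask[rows]
        return mask.sum(axis=0)


@dataclass
class AplSeries:
    values: np.ndarray  # nm² per frame
    denominator: str
    mean: float
    sd: float


def pl_tail_mean_z(system: SystemModel, frame: Frame, leaflet: Leaflet) -> float:
    """Unweighted mean z (nm) of all acyl tail carbons of a leaflet's PLs."""
    mols = [
        m for m in system.molecules_of_class(MoleculeClass.PL)
        if system.leaflets.get(m) is leaflet
    ]
    if not mols:
        raise ValueError(f"leaflet {leaflet.value} has no phospholipids")
    idx = system.select(roles=Role.ACYL_C, molecules=mols)
    if len(idx) == 0:
        raise ValueError(f"leaflet {leaflet.value}: no tagged acyl carbons")
    return float(np.mean(frame.coords[idx, 2]))


def _designated_oxygens(system: SystemModel, mol: int) -> np.ndarray:
    idx = system.molecules[mol]
    mc = system.mol_classes[mol]
    if mc is MoleculeClass.TG:
        mask = (system.roles[idx] & int(Role.ESTER_O | Role.GLYCEROL_O)) != 0
    else:
        mask = (system.roles[idx] & int(Role.ESTER_O)) != 0
    return idx[mask]


def classify_frame(
    system: SystemModel,
    frame: Frame,
    planes: tuple[float, float] | None = None,
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Label every neutral lipid SURF or CORE in one frame.

    Returns (molecule ids, surf flags, leaflet codes).  ``planes`` may carry
    precomputed (top, bottom) tail-plane z values.  Comparison is strictly
    above the top plane / strictly below the bottom plane.
    """
    if planes is None:
        planes = (
            pl_tail_mean_z(system, frame, Leaflet.TOP),
            pl_tail_mean_z(system, frame, Leaflet.BOTTOM),
        )
    top, bottom = planes
    mols = [
        m for m, c in enumerate(system.mol_classes) if c in NEUTRAL_LIPID_CLASSES
    ]
    surf = np.zeros(len(mols), dtype=bool)
    code = np.zeros(len(mols), dtype=np.int8)
    for k, m in enumerate(mols):
        ox = _designated_oxygens(system, m)
        z = frame.coords[ox, 2]
        above = bool(np.all(z > top))
        below = bool(np.all(z < bottom))
        if above and below:
            raise ValueError(
                f"molecule {m} straddles both tail planes (top={top}, bottom={bottom})"
            )
        if above:
            surf[k], code[k] = True, LEAFLET_CODE[Leaflet.TOP]
        elif below:
            surf[k], code[k] = True, LEAFLET_CODE[Leaflet.BOTTOM]
    return mols, surf, code


def classify(system: SystemModel, frames: list[Frame]) -> SurfLabelSeries:
    """SURF/CORE labels for every neutral lipid across a trajectory."""
    if not frames:
        raise ValueError("no frames")
    mols, _, _ = classify_frame(system, frames[0])
    n_m, n_f = len(mols), len(frames)
    surf = np.zeros((n_m, n_f), dtype=bool)
    code = np.zeros((n_m, n_f), dtype=np.int8)
    times = np.zeros(n_f)
    for j, fr in enumerate(frames):
        _, s, c = classify_frame(system, fr)
        surf[:, j], code[:, j] = s, c
        times[j] = fr.time
    return SurfLabelSeries(
        molecule_ids=mols,
        classes=[system.mol_classes[m] for m in mols],
        times=times,
        surf=surf,
        leaflet_code=code,
    )


def residence_filter(
    labels: SurfLabelSeries, min_duration: float = 5.0
) -> SurfLabelSeries:
    """Relabel SURF episodes shorter than ``min_duration`` (ns) as CORE.

    Episodes truncated by either trajectory end are censored and kept
    regardless of their observed length.  Idempotent.
    """
    t = labels.times
    if np.any(np.diff(t) <= 0):
        raise ValueError("frame times must be strictly increasing")
    out = labels.copy()
    n_f = len(t)
    for i in range(out.surf.shape[0]):
        row = out.surf[i]
        j = 0
        while j < n_f:
            if not row[j]:
                j += 1
                continue
            k = j
            while k + 1 < n_f and row[k + 1]:
                k += 1
            censored = j == 0 or k == n_f - 1
            if not censored and (t[k] - t[j]) < min_duration:
                row[j : k + 1] = False
                out.leaflet_code[i, j : k + 1] = 0
            j = k + 1
    return out


def monolayer_composition(
    labels: SurfLabelSeries,
    system: SystemModel,
    leaflet: Leaflet,
    denominator: str = "PL_PLUS_SURF",
    equilibration: float = 0.5,
) -> dict:
    """Time-averaged SURF-NL share of a monolayer.

    fraction = SURF-NL / (PL + SURF-NL) per frame (default denominator), or
    SURF-NL / PL with ``denominator='PL_ONLY'``; the first ``equilibration``
    fraction of frames is discarded.  Also reports the mean SURF count.
    """
    n_pl = sum(
        1 for m in system.molecules_of_class(MoleculeClass.PL)
        if system.leaflets.get(m) is leaflet
    )
    if n_pl == 0:
        raise ValueError(f"leaflet {leaflet.value} has no phospholipids")
    n_f = labels.surf.shape[1]
    lo = min(int(round(n_f * equilibration)), n_f - 1)
    counts = labels.surf_count(leaflet)[lo:]
    tg_counts = labels.surf_count(leaflet, MoleculeClass.TG)[lo:]
    chyo_counts = labels.surf_count(leaflet, MoleculeClass.CHYO)[lo:]
    if denominator == "PL_PLUS_SURF":
        frac = counts / (n_pl + counts)
    elif denominator == "PL_ONLY":
        frac = counts / n_pl
    else:
        raise ValueError("denominator must be PL_PLUS_SURF or PL_ONLY")
    return {
        "fraction": float(np.mean(frac)),
        "mean_surf_count": float(np.mean(counts)),
        "mean_surf_tg": float(np.mean(tg_counts)),
        "mean_surf_chyo": float(np.mean(chyo_counts)),
        "n_pl": n_pl,
        "denominator": denominator,
    }


def apl(
    system: SystemModel,
    frames: list[Frame],
    leaflet: Leaflet,
    components: str = "PL_ONLY",
    labels: SurfLabelSeries | None = None,
    equilibration: float = 0.5,
) -> AplSeries:
    """Area per lipid: leaflet x–y area over the number of components.

    ``components='PL_PLUS_SURF'`` adds the frame's SURF neutral lipids on
    that leaflet to the denominator (requires ``labels``).
    """
    n_pl = sum(
        1 for m in system.molecules_of_class(MoleculeClass.PL)
        if system.leaflets.get(m) is leaflet
    )
    if n_pl == 0:
        raise ValueError("zero components")
    if components == "PL_PLUS_SURF":
        if labels is None:
            raise ValueError("PL_PLUS_SURF requires a SurfLabelSeries")
        extra = labels.surf_count(leaflet)
    elif components == "PL_ONLY":
        extra = np.zeros(len(frames), dtype=int)
    else:
        raise ValueError("components must be PL_ONLY or PL_PLUS_SURF")
    vals = np.array(
        [fr.box[0] * fr.box[1] / (n_pl + extra[j]) for j, fr in enumerate(frames)]
    )
    n_f = len(vals)
    lo = min(int(round(n_f * equilibration)), n_f - 1)
    win = vals[lo:]
    return AplSeries(
        values=vals,
        denominator=components,
        mean=float(np.mean(win)),
        sd=float(np.std(win, ddof=1)) if len(win) > 1 else 0.0,
    )


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("series must have equal length of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    return float(stats.pearsonr(x, y).statistic)
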