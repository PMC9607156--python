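"""Monte Carlo Simulated Annealing fit of periodic dihedral force constants.

Fits a CHARMM-style periodic dihedral potential

    E(φ) = Σ_n k_n (1 + cos(n φ − δ_n)),   k_n ≥ 0, δ_n ∈ {0°, 180°}

(plus a free constant offset) to a target potential-energy scan, typically
the residual between a quantum-mechanical scan and the molecular-mechanics
scan with the unknown dihedral constants zeroed.  The search runs Metropolis
annealing with geometric cooling over the force constants and phases; at
the end the force constants are polished by non-negative least squares at
the best phases, which is exact because the model is linear in k given the
phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "DihedralScan",
    "DihedralTerm",
    "DihedralModel",
    "dihedral_energy",
    "mcsa_fit",
    "read_scan",
    "write_scan",
    "format_charmm_block",
]


@dataclass
class DihedralScan:
    """Target scan: strictly increasing angles (degrees) and energies
    (kcal/mol)."""

    angles: np.ndarray
    target_energy: np.ndarray

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.target_energy = np.asarray(self.target_energy, dtype=float)
        if self.angles.ndim != 1 or len(self.angles) != len(self.target_energy):
            raise ValueError("angles and energies must be equal-length 1-D arrays")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if not np.all(np.isfinite(self.target_energy)):
            raise ValueError("target energies must be finite")


@dataclass(frozen=True)
class DihedralTerm:
    multiplicity: int  # n in 1..6
    k: float  # kcal/mol, >= 0
    phase: float  # degrees, 0 or 180

    def __post_init__(self) -> None:
        if not 1 <= self.multiplicity <= 6:
            raise ValueError("multiplicity must be in 1..6")
        if self.k < 0:
            raise ValueError("force constants are non-negative")
        if self.phase not in (0.0, 180.0):
            raise ValueError("phase must be 0 or 180 degrees")


@dataclass
class DihedralModel:
    terms: list[DihedralTerm] = field(default_factory=list)

    def k_of(self, multiplicity: int) -> float:
        for t in self.terms:
            if t.multiplicity == multiplicity:
                return t.k
        return 0.0


def dihedral_energy(model: DihedralModel, phi) -> np.ndarray | float:
    """E(φ) = Σ k_n (1 + cos(nφ − δ_n)); φ in degrees."""
    phi_r = np.deg2rad(np.asarray(phi, dtype=float))
    e = np.zeros_like(phi_r)
    for t in model.terms:
        e = e + t.k * (1.0 + np.cos(t.multiplicity * phi_r - np.deg2rad(t.phase)))
    return float(e) if np.ndim(phi) == 0 else e


def _design(angles: np.ndarray, mult: list[int], phases: np.ndarray) -> np.ndarray:
    phi = np.deg2rad(angles)
    cols = [1.0 + np.cos(n * phi - np.deg2rad(d)) for n, d in zip(mult, phases)]
    return np.array(cols).T


def _rmse(design: np.ndarray, ks: np.ndarray, target: np.ndarray) -> float:
    resid = target - design @ ks
    resid = resid - resid.mean()  # free constant offset
    return float(np.sqrt(np.mean(resid**2)))


def mcsa_fit(
    scan: DihedralScan,
    multiplicities: list[int] = (1, 2, 3, 6),
    t0: float = 5.0,
    cooling: float = 0.95,
    steps_per_temp: int = 200,
    t_min: float = 1e-4,
    seed: int | None = None,
    k_max: float = 20.0,
    polish: bool = True,
) -> tuple[DihedralModel, float]:
    """Fit force constants and phases to a scan by simulated annealing.

    Metropolis proposals perturb one randomly chosen force constant by a
    temperature-scaled Gaussian step or flip one phase (probability 0.1);
    acceptance follows exp(−ΔRMSE/T) with geometric cooling T ← cooling·T.
    The best-ever solution is tracked and, with ``polish``, its force
    constants are refined by non-negative least squares at the best phases.
    Returns (model, rmse in kcal/mol).
    """
    multiplicities = list(multiplicities)
    if not multiplicities:
        raise ValueError("need at least one multiplicity")
    m = len(multiplicities)
    if len(scan.angles) < 2 * (m + 1):
        raise ValueError("scan must have at least twice as many points as parameters")
    rng = np.random.default_rng(seed)
    target = scan.target_energy - scan.target_energy.min()

    phases = np.zeros(m)
    ks = np.abs(rng.normal(0.5, 0.5, size=m))
    design = _design(scan.angles, multiplicities, phases)
    cur = _rmse(design, ks, target)
    best_ks, best_phases, best = ks.copy(), phases.copy(), cur

    temp = t0
    while temp > t_min:
        for _ in range(steps_per_temp):
            new_ks, new_phases = ks.copy(), phases.copy()
            j = rng.integers(m)
            if rng.random() < 0.1:
                new_phases[j] = 180.0 - new_phases[j]
                design_new = _design(scan.angles, multiplicities, new_phases)
            else:
                step = max(0.02, 0.3 * temp / t0)
                new_ks[j] = np.clip(new_ks[j] + rng.normal(0.0, step), 0.0, k_max)
                design_new = (
                    design
                    if np.array_equal(new_phases, phases)
                    else _design(scan.angles, multiplicities, new_phases)
                )
            cand = _rmse(design_new, new_ks, target)
            if cand < cur or rng.random() < np.exp(-(cand - cur) / temp):
                ks, phases, cur, design = new_ks, new_phases, cand, design_new
                if cur < best:
                    best_ks, best_phases, best = ks.copy(), phases.copy(), cur
        temp *= cooling

    if polish:
        design = _design(scan.angles, multiplicities, best_phases)
        # offset column is unconstrained: solve with centred columns via NNLS
        # on [design, 1] split into +/- offset parts
        aug = np.column_stack([design, np.ones(len(target)), -np.ones(len(target))])
        sol, _ = nnls(aug, target)
        cand_ks = sol[:m]
        cand = _rmse(design, cand_ks, target)
        if cand <= best:
            best_ks, best = cand_ks, cand

    model = DihedralModel(
        terms=[
            DihedralTerm(n, float(k), float(d))
            for n, k, d in zip(multiplicities, best_ks, best_phases)
        ]
    )
    return model, best


def read_scan(path) -> DihedralScan:
    """Read a two-column (angle°, energy kcal/mol) plain-text scan."""
    data = np.loadtxt(path)
    return DihedralScan(data[:, 0], data[:, 1])


def write_scan(path, scan: DihedralScan) -> None:
    np.savetxt(
        path,
        np.column_stack([scan.angles, scan.target_energy]),
        header="angle_deg energy_kcal_mol",
    )


def format_charmm_block(
    model: DihedralModel, atom_types: tuple[str, str, str, str] = ("X", "A", "B", "X")
) -> str:
    """CHARMM-style dihedral parameter lines for the fitted terms."""
    lines = []
    for t in model.terms:
        lines.append(
            f"{atom_types[0]:<6}{atom_types[1]:<6}{atom_types[2]:<6}"
            f"{atom_types[3]:<6}{t.k:10.4f}{t.multiplicity:4d}{t.phase:8.1f}"
        )
    return "\n".join(lines)
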