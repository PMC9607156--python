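"""Domain model for trilayer lipid-droplet analysis.

Defines the static topology (:class:`SystemModel`), per-frame coordinates
(:class:`Frame`), the residue/atom role mapping that assigns each atom a
molecule class (phospholipid, triacylglycerol, sterol ester, water, ion) and
a set of functional roles (head group, phosphorus, ester/glycerol oxygen,
acyl carbon/hydrogen, sterol ring/side chain), and I/O through MDAnalysis
for GRO/PDB coordinates and XTC/DCD trajectories.

Internally all coordinates and box lengths are nanometres and times are
nanoseconds; van der Waals radii are kept in angstroms because the packing
defect grid works on a 1 Å lattice.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum, IntFlag, auto
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "MoleculeClass",
    "Role",
    "Leaflet",
    "AtomRecord",
    "Frame",
    "SystemModel",
    "RoleMap",
    "RoleMapError",
    "TopologyError",
    "load_role_map",
    "default_role_map",
    "load_system",
    "load_frame",
    "assign_leaflets",
    "read_trajectory",
    "write_gro",
    "write_xtc",
    "build_system",
]


class MoleculeClass(Enum):
    PL = "PL"
    TG = "TG"
    CHYO = "CHYO"
    WATER = "WATER"
    ION = "ION"


NEUTRAL_LIPID_CLASSES = (MoleculeClass.TG, MoleculeClass.CHYO)
LIPID_CLASSES = (MoleculeClass.PL, MoleculeClass.TG, MoleculeClass.CHYO)


class Role(IntFlag):
    """Functional atom roles; an atom may carry several."""

    HEAD = auto()
    PHOSPHORUS = auto()
    GLYCEROL_O = auto()
    ESTER_O = auto()
    ACYL_C = auto()
    ACYL_H = auto()
    STEROL_RING = auto()
    STEROL_SIDE = auto()
    WATER_O = auto()


class Leaflet(Enum):
    TOP = "TOP"
    BOTTOM = "BOTTOM"
    NONE = "NONE"


# Bondi-style van der Waals radii, angstroms.  "W" is the single-site
# pseudo-water used by the synthetic generator.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "NA": 2.27,
    "CL": 1.75,
    "K": 2.75,
    "W": 1.70,
}

# Atomic masses, g/mol.
MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "W": 18.015,
}


class RoleMapError(ValueError):
    """Raised when a residue or atom cannot be resolved by the role map."""


class TopologyError(ValueError):
    """Raised when a molecule violates a class invariant."""


@dataclass(frozen=True)
class AtomRecord:
    atom_index: int
    atom_name: str
    element: str
    residue_name: str
    residue_index: int
    molecule_class: MoleculeClass
    role_tags: Role
    vdw_radius: float  # angstrom
    mass: float  # g/mol


@dataclass
class Frame:
    """Coordinates (nm) in an orthorhombic box (nm) at a time stamp (ns)."""

    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)


class SystemModel:
    """Static topology: atoms, molecules, classes, roles, leaflet tags.

    Atom attributes are stored as flat numpy arrays for vectorized
    selection; :meth:`atom` materializes an :class:`AtomRecord` view.
    """

    def __init__(
        self,
        names: np.ndarray,
        elements: np.ndarray,
        resnames: np.ndarray,
        resids: np.ndarray,
        mol_class_codes: np.ndarray,
        roles: np.ndarray,
        radii: np.ndarray,
        masses: np.ndarray,
        molecules: list[np.ndarray],
        mol_classes: list[MoleculeClass],
    ) -> None:
        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.resnames = np.asarray(resnames, dtype=object)
        self.resids = np.asarray(resids, dtype=int)
        self.mol_class_codes = np.asarray(mol_class_codes, dtype=object)
        self.roles = np.asarray(roles, dtype=np.int64)
        self.radii = np.asarray(radii, dtype=float)
        self.masses = np.asarray(masses, dtype=float)
        self.molecules = [np.asarray(m, dtype=int) for m in molecules]
        self.mol_classes = list(mol_classes)
        self.leaflets: dict[int, Leaflet] = {}
        self._validate()

    # -- construction ---------------------------------------------------

    def _validate(self) -> None:
        n = len(self.names)
        counted = np.concatenate(self.molecules) if self.molecules else np.array([], int)
        if len(counted) != n or len(np.unique(counted)) != n:
            raise TopologyError("molecules must partition the atom set")
        if np.any(self.radii <= 0):
            raise TopologyError("all vdW radii must be positive")
        for mi, (idx, mc) in enumerate(zip(self.molecules, self.mol_classes)):
            r = self.roles[idx]
            if mc is MoleculeClass.TG:
                n_ox = int(np.sum((r & (Role.ESTER_O | Role.GLYCEROL_O)) != 0))
                if n_ox != 6:
                    raise TopologyError(
                        f"TG molecule {mi} ({self.resnames[idx[0]]}:{self.resids[idx[0]]}) "
                        f"has {n_ox} tagged ester/glycerol oxygens, expected exactly 6"
                    )
            elif mc is MoleculeClass.CHYO:
                n_est = int(np.sum((r & Role.ESTER_O) != 0))
                if n_est != 2:
                    raise TopologyError(
                        f"CHYO molecule {mi} has {n_est} ester oxygens, expected exactly 2"
                    )

    # -- accessors ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            atom_index=i,
            atom_name=self.names[i],
            element=self.elements[i],
            residue_name=self.resnames[i],
            residue_index=int(self.resids[i]),
            molecule_class=self.mol_class_codes[i],
            role_tags=Role(int(self.roles[i])),
            vdw_radius=float(self.radii[i]),
            mass=float(self.masses[i]),
        )

    def molecules_of_class(self, mclass: MoleculeClass) -> list[int]:
        return [i for i, c in enumerate(self.mol_classes) if c is mclass]

    def select(
        self,
        mclass: MoleculeClass | Iterable[MoleculeClass] | None = None,
        roles: Role | None = None,
        molecules: Iterable[int] | None = None,
    ) -> np.ndarray:
        """Atom indices filtered by class, role mask, and/or molecule ids."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if mclass is not None:
            classes = (mclass,) if isinstance(mclass, MoleculeClass) else tuple(mclass)
            cmask = np.zeros(self.n_atoms, dtype=bool)
            for c in classes:
                cmask |= np.array([mc is c for mc in self.mol_class_codes])
            mask &= cmask
        if roles is not None:
            mask &= (self.roles & int(roles)) != 0
        if molecules is not None:
            mmask = np.zeros(self.n_atoms, dtype=bool)
            for m in molecules:
                mmask[self.molecules[m]] = True
            mask &= mmask
        return np.nonzero(mask)[0]

    def leaflet_molecules(self, leaflet: Leaflet) -> list[int]:
        return [m for m, lf in self.leaflets.items() if lf is leaflet]

    def copy(self) -> "SystemModel":
        out = SystemModel(
            self.names.copy(), self.elements.copy(), self.resnames.copy(),
            self.resids.copy(), self.mol_class_codes.copy(), self.roles.copy(),
            self.radii.copy(), self.masses.copy(),
            [m.copy() for m in self.molecules], list(self.mol_classes),
        )
        out.leaflets = dict(self.leaflets)
        return out


# ---------------------------------------------------------------------------
# Role map
# ---------------------------------------------------------------------------


class RoleMap:
    """Residue-name → class / atom-role mapping, loaded from YAML.

    Schema::

        residues:
          <RESNAME>:
            class: PL|TG|CHYO|WATER|ION
            roles:
              <ROLE>: [<atom name or fnmatch pattern>, ...]
            elements: {<atom pattern>: <element symbol>}   # optional
            radii:    {<atom pattern>: <angstrom>}         # optional
            masses:   {<atom pattern>: <g/mol>}            # optional

    An atom may match several role patterns; roles are unioned.  Elements
    default to the leading alphabetic part of the atom name (two-letter
    symbols like NA/CL are recognized first).
    """

    def __init__(self, spec: dict) -> None:
        if "residues" not in spec:
            raise RoleMapError("role map must have a top-level 'residues' key")
        self.residues: dict[str, dict] = {}
        for resname, block in spec["residues"].items():
            try:
                mclass = MoleculeClass(block["class"])
            except (KeyError, ValueError) as exc:
                raise RoleMapError(f"residue {resname}: bad or missing class") from exc
            roles = {}
            for role_name, patterns in (block.get("roles") or {}).items():
                try:
                    role = Role[role_name]
                except KeyError as exc:
                    raise RoleMapError(
                        f"residue {resname}: unknown role {role_name}"
                    ) from exc
                roles[role] = list(patterns)
            self.residues[resname] = {
                "class": mclass,
                "roles": roles,
                "elements": dict(block.get("elements") or {}),
                "radii": dict(block.get("radii") or {}),
                "masses": dict(block.get("masses") or {}),
            }

    def has_residue(self, resname: str) -> bool:
        return resname in self.residues

    @staticmethod
    def _lookup(table: dict, name: str):
        for pattern, value in table.items():
            if fnmatch.fnmatchcase(name, pattern):
                return value
        return None

    @staticmethod
    def infer_element(name: str) -> str:
        alpha = "".join(ch for ch in name if ch.isalpha()).upper()
        if alpha[:2] in ("NA", "CL"):
            return alpha[:2]
        if not alpha:
            raise RoleMapError(f"cannot infer an element from atom name {name!r}")
        return alpha[0]

    def resolve(self, resname: str, atomname: str):
        """Return (class, roles, element, radius Å, mass) for one atom."""
        if resname not in self.residues:
            raise RoleMapError(
                f"residue {resname!r} is not covered by the role map"
            )
        block = self.residues[resname]
        roles = Role(0)
        for role, patterns in block["roles"].items():
            for pattern in patterns:
                if fnmatch.fnmatchcase(atomname, pattern):
                    roles |= role
                    break
        element = self._lookup(block["elements"], atomname) or self.infer_element(atomname)
        element = element.upper()
        radius = self._lookup(block["radii"], atomname)
        if radius is None:
            if element not in VDW_RADII:
                raise RoleMapError(
                    f"no vdW radius for element {element!r} (atom {atomname})"
                )
            radius = VDW_RADII[element]
        mass = self._lookup(block["masses"], atomname)
        if mass is None:
            if element not in MASSES:
                raise RoleMapError(f"no mass for element {element!r} (atom {atomname})")
            mass = MASSES[element]
        return block["class"], roles, element, float(radius), float(mass)


def load_role_map(source: str | Path | dict | RoleMap) -> RoleMap:
    """Load a role map from a YAML path, a bundled map name (``synthetic``
    or ``charmm36``), or an equivalent dict."""
    if isinstance(source, RoleMap):
        return source
    if isinstance(source, dict):
        return RoleMap(source)
    bundled = resources.files("ldtk.data") / f"roles_{source}.yaml"
    if isinstance(source, str) and not Path(source).exists() and bundled.is_file():
        return RoleMap(yaml.safe_load(bundled.read_text()))
    with open(source) as fh:
        return RoleMap(yaml.safe_load(fh))


def default_role_map(name: str = "synthetic") -> RoleMap:
    """Shipped role maps: ``synthetic`` (generator pseudo-molecules) or
    ``charmm36`` (POPC/DOPE/SAPI/triolein/cholesteryl-oleate naming)."""
    ref = resources.files("ldtk.data") / f"roles_{name}.yaml"
    return RoleMap(yaml.safe_load(ref.read_text()))


# ---------------------------------------------------------------------------
# Construction and I/O
# ---------------------------------------------------------------------------


def build_system(
    names: Sequence[str],
    resnames: Sequence[str],
    resids: Sequence[int],
    role_map: RoleMap,
) -> SystemModel:
    """Assemble a SystemModel from parallel atom arrays.

    Molecules are contiguous runs of a constant (resid, resname) pair, the
    convention of GRO/PDB residue numbering.
    """
    names = np.asarray(names, dtype=object)
    resnames = np.asarray(resnames, dtype=object)
    resids = np.asarray(resids, dtype=int)
    n = len(names)
    elements = np.empty(n, dtype=object)
    classes = np.empty(n, dtype=object)
    roles = np.zeros(n, dtype=np.int64)
    radii = np.zeros(n)
    masses = np.zeros(n)
    for i in range(n):
        mclass, role, element, radius, mass = role_map.resolve(resnames[i], names[i])
        classes[i] = mclass
        roles[i] = int(role)
        elements[i] = element
        radii[i] = radius
        masses[i] = mass

    molecules: list[np.ndarray] = []
    mol_classes: list[MoleculeClass] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or resids[i] != resids[start] or resnames[i] != resnames[start]:
            molecules.append(np.arange(start, i))
            mol_classes.append(classes[start])
            start = i
    return SystemModel(
        names, elements, resnames, resids, classes, roles, radii, masses,
        molecules, mol_classes,
    )


def _mda_universe(path: str | Path, *args, **kwargs):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path), *args, **kwargs)


def load_system(coord_file: str | Path, role_map: RoleMap | str | Path | dict) -> SystemModel:
    """Read a GRO or PDB file and resolve classes/roles for every atom.

    Raises :class:`RoleMapError` if any residue name in the file is absent
    from the role map, and :class:`TopologyError` on class-invariant
    violations (e.g. a TG without exactly six tagged oxygens).
    """
    if not isinstance(role_map, RoleMap):
        role_map = load_role_map(role_map)
    u = _mda_universe(coord_file)
    missing = sorted(
        {rn for rn in u.atoms.resnames if not role_map.has_residue(rn)}
    )
    if missing:
        raise RoleMapError(
            f"residues not covered by the role map: {', '.join(missing)}"
        )
    return build_system(
        [str(nm) for nm in u.atoms.names],
        [str(rn) for rn in u.atoms.resnames],
        u.atoms.resids,
        role_map,
    )


def load_frame(coord_file: str | Path) -> Frame:
    """Read the coordinates of a GRO/PDB file as a Frame (nm)."""
    u = _mda_universe(coord_file)
    box = u.dimensions
    if box is None or np.any(box[:3] <= 0):
        raise ValueError(f"{coord_file}: no valid box dimensions")
    return Frame(u.atoms.positions / 10.0, np.asarray(box[:3]) / 10.0, 0.0)


def read_trajectory(
    traj_file: str | Path,
    system: SystemModel,
    topology_file: str | Path | None = None,
    start: int = 0,
    stop: int | None = None,
    stride: int = 1,
) -> list[Frame]:
    """Read frames (nm/ns) from an XTC or DCD trajectory in time order."""
    import MDAnalysis as mda

    path = Path(traj_file)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if topology_file is not None:
            u = mda.Universe(str(topology_file), str(path))
        else:
            u = mda.Universe(str(path), to_guess=())
    if len(u.atoms) != system.n_atoms:
        raise ValueError(
            f"trajectory has {len(u.atoms)} atoms, system has {system.n_atoms}"
        )
    frames = [
        Frame(ts.positions / 10.0, np.asarray(ts.dimensions[:3]) / 10.0,
              float(ts.time) / 1000.0)
        for ts in u.trajectory[start:stop:stride]
    ]
    if not frames:
        warnings.warn("trajectory slice produced no frames", stacklevel=2)
    return frames


def _empty_universe(system: SystemModel, n_frames: int = 1):
    import MDAnalysis as mda

    resindex = np.zeros(system.n_atoms, dtype=int)
    for mi, idx in enumerate(system.molecules):
        resindex[idx] = mi
    u = mda.Universe.empty(
        system.n_atoms,
        n_residues=system.n_molecules,
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in system.names])
    u.add_TopologyAttr(
        "resnames", [str(system.resnames[idx[0]]) for idx in system.molecules]
    )
    u.add_TopologyAttr(
        "resids", [int(system.resids[idx[0]]) for idx in system.molecules]
    )
    return u


def write_gro(path: str | Path, system: SystemModel, frame: Frame) -> None:
    """Write one frame as a GRO file (format precision: 0.001 nm)."""
    u = _empty_universe(system)
    u.atoms.positions = frame.coords * 10.0
    u.dimensions = [*(frame.box * 10.0), 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_xtc(path: str | Path, system: SystemModel, frames: Iterable[Frame]) -> None:
    """Write a frame sequence as an XTC trajectory."""
    import MDAnalysis as mda

    u = _empty_universe(system)
    frames = list(frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=system.n_atoms) as w:
            for fr in frames:
                u.atoms.positions = fr.coords * 10.0
                u.dimensions = [*(fr.box * 10.0), 90.0, 90.0, 90.0]
                u.trajectory.ts.time = fr.time * 1000.0
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# Leaflet assignment
# ---------------------------------------------------------------------------


def assign_leaflets(system: SystemModel, frame: Frame) -> SystemModel:
    """Tag every PL molecule TOP or BOTTOM relative to the core midplane.

    The midplane is the mean z of all neutral-lipid atoms; a PL whose
    phosphorus sits above it is TOP.  Returns a copy with leaflet tags set.
    """
    out = system.copy()
    nl_atoms = system.select(mclass=NEUTRAL_LIPID_CLASSES)
    if len(nl_atoms) == 0:
        raise TopologyError("cannot locate the core midplane: no neutral lipids")
    midplane = float(np.mean(frame.coords[nl_atoms, 2]))
    for m in system.molecules_of_class(MoleculeClass.PL):
        idx = system.molecules[m]
        p = idx[(system.roles[idx] & int(Role.PHOSPHORUS)) != 0]
        if len(p) == 0:
            raise TopologyError(f"PL molecule {m} has no phosphorus atom")
        z = float(np.mean(frame.coords[p, 2]))
        out.leaflets[m] = Leaflet.TOP if z > midplane else Leaflet.BOTTOM
    return out


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return d - box * np.round(d / box)
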