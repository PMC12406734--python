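"""Topologies, multi-model PDB trajectories, and atom chemistry roles.

The native trajectory format is multi-model PDB: the first MODEL defines the
topology (atom names, residues, chains) and every subsequent MODEL supplies
one coordinate frame.  Binary trajectory formats can be plugged in through
:func:`trajectory_from_frames`, which accepts any iterable of ``(n_atoms, 3)``
coordinate arrays in Angstrom.

Chemistry roles (hydrogen-bond donors/acceptors with their acceptor
antecedents, and the charged side-chain groups used for salt bridges) come
from editable tab-separated tables shipped with the package, never from
distance-based inference.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger("mdinet")
# MDAnalysis element/mass guessing chatter is irrelevant to pipeline logs
logging.getLogger("MDAnalysis").setLevel(logging.WARNING)

# Atomic masses (u) for the elements occurring in amino-acid templates;
# used for charged-group centers of mass.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}

#: Atom-name selection used for backbone RMSD/RMSF.
BACKBONE_SELECTION = frozenset({"N", "CA", "C", "O"})

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Role tags attached to atoms by assign_roles().
ROLE_ACIDIC_O = "acidic-O"
ROLE_BASIC_N = "basic-N"
ROLE_DONOR = "donor-heavy"
ROLE_DONOR_H = "donor-H"
ROLE_ACCEPTOR = "acceptor"
ROLE_ANTECEDENT = "antecedent"


class PDBParseError(ValueError):
    """Raised when a multi-model PDB file violates the format contract."""


class TopologyError(ValueError):
    """Raised when a system violates a topology invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """One atom of a molecular system (author numbering, file order)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    is_hydrogen: bool
    roles: frozenset[str] = frozenset()

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element, 12.011)

    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_name}{self.residue_number}:{self.name}"


@dataclass(frozen=True)
class MolecularSystem:
    """An ordered atom list with residue identity and template bonds.

    Bonds come from the shipped residue templates (tree bonds plus the
    inter-residue peptide C-N bond); they are stored as a symmetric set of
    index pairs and never inferred from distances.
    """

    atoms: tuple[Atom, ...]
    bonds: frozenset[tuple[int, int]] = frozenset()
    label: str = ""
    nonstandard_residues: frozenset[tuple[str, int, str]] = frozenset()

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.name)
            if key in seen:
                raise TopologyError(f"duplicate atom {a.label()} in system")
            seen.add(key)
        for i, j in self.bonds:
            if i == j:
                raise TopologyError(f"self-bond on atom index {i}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[tuple[str, int, str]]:
        """(chain_id, residue_number, residue_name), in file order."""
        out: list[tuple[str, int, str]] = []
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.residue_name)
            if not out or out[-1] != key:
                out.append(key)
        return out

    def atom_index(self, chain_id: str, residue_number: int, name: str) -> int:
        try:
            return self._index_map[(chain_id, residue_number, name)]
        except KeyError as exc:
            raise KeyError(
                f"no atom {chain_id}:{residue_number}:{name} in system {self.label!r}"
            ) from exc

    @property
    def _index_map(self) -> dict[tuple[str, int, str], int]:
        cached = getattr(self, "_index_map_cache", None)
        if cached is None:
            cached = {
                (a.chain_id, a.residue_number, a.name): i
                for i, a in enumerate(self.atoms)
            }
            object.__setattr__(self, "_index_map_cache", cached)
        return cached

    def bonded_to(self, index: int) -> list[int]:
        return sorted(j for i, j in self.bonds if i == index)

    def atoms_of_residue(self, chain_id: str, residue_number: int) -> list[int]:
        return [
            i for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]

    def with_atoms(self, atoms: Sequence[Atom]) -> "MolecularSystem":
        return dataclasses.replace(self, atoms=tuple(atoms))


@dataclass
class Trajectory:
    """One replicate: ``(n_frames, n_atoms, 3)`` coordinates in Angstrom."""

    system: MolecularSystem
    coordinates: np.ndarray
    frame_interval_ps: float = 10.0
    replicate_id: int = 1

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must be (frames, atoms, 3), got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise ValueError("a trajectory needs at least 1 frame")
        if self.coordinates.shape[1] != self.system.n_atoms:
            raise ValueError(
                f"frame has {self.coordinates.shape[1]} atoms, "
                f"system has {self.system.n_atoms}"
            )
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite coordinates in trajectory")
        if self.frame_interval_ps <= 0:
            raise ValueError("frame_interval_ps must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_ps


@dataclass
class Ensemble:
    """Replicate trajectories per system label, with a designated reference."""

    systems: dict[str, list[Trajectory]]
    reference_label: str

    def __post_init__(self) -> None:
        if self.reference_label not in self.systems:
            raise ValueError(
                f"reference label {self.reference_label!r} not among systems "
                f"{sorted(self.systems)}"
            )
        for label, reps in self.systems.items():
            if not reps:
                raise ValueError(f"system {label!r} has no replicates")
            names = [a.name for a in reps[0].system.atoms]
            for t in reps[1:]:
                if [a.name for a in t.system.atoms] != names:
                    raise ValueError(
                        f"replicates of {label!r} differ in atom ordering"
                    )

    @property
    def labels(self) -> list[str]:
        return list(self.systems)

    @property
    def variant_labels(self) -> list[str]:
        return [l for l in self.systems if l != self.reference_label]


@dataclass(frozen=True)
class ChemistryRoles:
    """Role tables driving H-bond and salt-bridge atom selection.

    All four maps are keyed by 3-letter residue name.  ``hbond_donors`` maps
    to ``(heavy atom, hydrogens)`` pairs, ``hbond_acceptors`` to
    ``(acceptor, antecedent)`` pairs (exactly one antecedent per acceptor).
    """

    acidic_oxygens: Mapping[str, tuple[str, ...]]
    basic_nitrogens: Mapping[str, tuple[str, ...]]
    hbond_donors: Mapping[str, tuple[tuple[str, tuple[str, ...]], ...]]
    hbond_acceptors: Mapping[str, tuple[tuple[str, str], ...]]

    @staticmethod
    def from_table(path: str | Path) -> "ChemistryRoles":
        acidic: dict[str, list[str]] = {}
        basic: dict[str, list[str]] = {}
        donors: dict[str, list[tuple[str, tuple[str, ...]]]] = {}
        acceptors: dict[str, list[tuple[str, str]]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("residue\t"):
                continue
            res, atom, role, partner = line.split("\t")
            if role == "acidic_o":
                acidic.setdefault(res, []).append(atom)
            elif role == "basic_n":
                basic.setdefault(res, []).append(atom)
            elif role == "donor":
                donors.setdefault(res, []).append(
                    (atom, tuple(partner.split(",")))
                )
            elif role == "acceptor":
                acceptors.setdefault(res, []).append((atom, partner))
            else:
                raise ValueError(f"unknown role {role!r} in {path}")
        return ChemistryRoles(
            acidic_oxygens={r: tuple(v) for r, v in acidic.items()},
            basic_nitrogens={r: tuple(v) for r, v in basic.items()},
            hbond_donors={r: tuple(v) for r, v in donors.items()},
            hbond_acceptors={r: tuple(v) for r, v in acceptors.items()},
        )

    @staticmethod
    def default(include_histidine_basic: bool = False) -> "ChemistryRoles":
        """Roles from the shipped table.

        Histidine nitrogens are excluded from the basic (salt-bridge) group
        by default because their charge is protonation-state dependent;
        ``include_histidine_basic=True`` adds HIS ND1/NE2.
        """
        with resources.as_file(
            resources.files("mdinet.data") / "residue_chemistry.tsv"
        ) as p:
            roles = ChemistryRoles.from_table(p)
        if include_histidine_basic:
            basic = dict(roles.basic_nitrogens)
            basic["HIS"] = ("ND1", "NE2")
            roles = dataclasses.replace(roles, basic_nitrogens=basic)
        return roles


# ---------------------------------------------------------------------------
# Residue templates (atoms + bonds)
# ---------------------------------------------------------------------------

def load_residue_templates() -> dict[str, list[tuple[str, str, str]]]:
    """residue -> ordered [(atom, element, parent)]; parent '-' means none."""
    templates: dict[str, list[tuple[str, str, str]]] = {}
    with resources.as_file(
        resources.files("mdinet.data") / "residue_templates.tsv"
    ) as path:
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("residue\t"):
                continue
            res, atom, element, parent = line.split("\t")
            templates.setdefault(res, []).append((atom, element, parent))
    return templates


def template_bonds(system: MolecularSystem) -> frozenset[tuple[int, int]]:
    """Symmetric bond set from residue templates plus peptide C-N links.

    Atoms of residues without a template get no bonds (the residue is flagged
    nonstandard by the caller); bonds are never inferred from distances.
    """
    templates = load_residue_templates()
    pairs: set[tuple[int, int]] = set()
    index = {(a.chain_id, a.residue_number, a.name): i for i, a in enumerate(system.atoms)}
    residues = system.residues
    for chain, resnum, resname in residues:
        tpl = templates.get(resname)
        if tpl is None:
            continue
        for atom, _element, parent in tpl:
            if parent == "-":
                continue
            i = index.get((chain, resnum, atom))
            j = index.get((chain, resnum, parent))
            if i is not None and j is not None:
                pairs.add((i, j))
                pairs.add((j, i))
    # peptide bond: C(i) - N(i+1) within a chain, consecutive residue numbers
    for (c1, r1, _n1), (c2, r2, _n2) in zip(residues, residues[1:]):
        if c1 == c2 and r2 == r1 + 1:
            i = index.get((c1, r1, "C"))
            j = index.get((c2, r2, "N"))
            if i is not None and j is not None:
                pairs.add((i, j))
                pairs.add((j, i))
    return frozenset(pairs)


def _element_from_name(name: str, resname: str) -> str:
    """Element symbol from a PDB atom name when no element column is given."""
    stripped = name.strip()
    if stripped[:1].isdigit():
        stripped = stripped[1:]
    if stripped[:1] == "H":
        return "H"
    for el in ("CL", "BR", "NA", "MG", "ZN", "MN", "FE", "CA"):
        # two-letter ions only in HET context; amino-acid CA is carbon
        if resname not in _STANDARD_RESIDUES and stripped.upper() == el:
            return el.capitalize()
    return stripped[:1]


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _universe_to_system(u, label: str) -> MolecularSystem:
    atoms: list[Atom] = []
    has_elements = hasattr(u.atoms, "elements")
    for i, a in enumerate(u.atoms):
        resname = str(a.resname).strip()
        element = (
            str(a.element).strip().capitalize()
            if has_elements and str(a.element).strip()
            else _element_from_name(str(a.name), resname)
        )
        chain = str(getattr(a, "chainID", "") or getattr(a, "segid", "") or "A").strip() or "A"
        atoms.append(
            Atom(
                serial=i + 1,
                name=str(a.name).strip(),
                element=element,
                residue_name=resname,
                residue_number=int(a.resid),
                chain_id=chain[0],
                is_hydrogen=element == "H",
            )
        )
    nonstandard = frozenset(
        (c, n, r)
        for (c, n, r) in _residues_of(atoms)
        if r not in _STANDARD_RESIDUES
    )
    system = MolecularSystem(
        atoms=tuple(atoms), label=label, nonstandard_residues=nonstandard
    )
    return dataclasses.replace(system, bonds=template_bonds(system))


def _residues_of(atoms: Sequence[Atom]) -> list[tuple[str, int, str]]:
    out: list[tuple[str, int, str]] = []
    for a in atoms:
        key = (a.chain_id, a.residue_number, a.residue_name)
        if not out or out[-1] != key:
            out.append(key)
    return out


def _check_coordinate_fields(path: Path) -> None:
    """Locate the first malformed ATOM coordinate field, for error reporting."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                field_text = line[lo:hi]
                try:
                    float(field_text)
                except ValueError:
                    raise PDBParseError(
                        f"{path}: unparseable coordinate field {field_text!r} "
                        f"on line {lineno}"
                    ) from None


def load_multimodel_pdb(
    path: str | Path,
    label: str | None = None,
    frame_interval_ps: float = 10.0,
    replicate_id: int = 1,
) -> Trajectory:
    """Read a multi-model PDB file as one replicate trajectory.

    MODEL 1 defines the topology; every MODEL must repeat the same atoms in
    the same order.  Coordinates are returned in Angstrom.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_coordinate_fields(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # re-raise with file context
            raise PDBParseError(f"{path}: {exc}") from exc
        system = _universe_to_system(u, label or path.stem)
        frames: list[np.ndarray] = []
        try:
            for ts in u.trajectory:
                frames.append(np.array(ts.positions, dtype=float))
        except Exception as exc:
            raise PDBParseError(
                f"{path}: MODEL {len(frames) + 1} does not match the atom "
                f"count/ordering of MODEL 1 ({exc})"
            ) from exc
    if system.nonstandard_residues:
        logger.warning(
            "%s: nonstandard residues without templates: %s",
            path,
            sorted(system.nonstandard_residues),
        )
    return Trajectory(
        system=system,
        coordinates=np.stack(frames),
        frame_interval_ps=frame_interval_ps,
        replicate_id=replicate_id,
    )


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> Path:
    """Write one MODEL/ENDMDL block per frame, coordinates to 3 decimals."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    path = Path(path)
    system = trajectory.system
    n = system.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n,
            n_residues=len(system.residues),
            atom_resindex=_atom_resindex(system),
            residue_segindex=np.zeros(len(system.residues), dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in system.atoms])
        u.add_TopologyAttr("elements", [a.element for a in system.atoms])
        u.add_TopologyAttr("resnames", [r[2] for r in system.residues])
        u.add_TopologyAttr("resids", [r[1] for r in system.residues])
        u.add_TopologyAttr("chainIDs", [a.chain_id for a in system.atoms])
        u.add_TopologyAttr("segids", ["SYS"])
        u.add_TopologyAttr("occupancies", np.ones(n))
        u.add_TopologyAttr("tempfactors", np.zeros(n))
        u.load_new(
            np.asarray(trajectory.coordinates, dtype=np.float32), format=MemoryReader
        )
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for _ts in u.trajectory:
                w.write(u.atoms)
    return path


def _atom_resindex(system: MolecularSystem) -> np.ndarray:
    residues = system.residues
    rmap = {(c, n): i for i, (c, n, _r) in enumerate(residues)}
    return np.array([rmap[a.residue_key] for a in system.atoms], dtype=int)


def trajectory_from_frames(
    system: MolecularSystem,
    frames: Iterable[np.ndarray],
    frame_interval_ps: float = 10.0,
    replicate_id: int = 1,
) -> Trajectory:
    """Adapter hook: build a Trajectory from any frame iterator.

    ``frames`` yields ``(n_atoms, 3)`` arrays in Angstrom — the contract a
    binary-format reader (e.g. an mdtraj or MDAnalysis iterator) must meet.
    """
    coords = np.stack([np.asarray(f, dtype=float) for f in frames])
    return Trajectory(
        system=system,
        coordinates=coords,
        frame_interval_ps=frame_interval_ps,
        replicate_id=replicate_id,
    )


# ---------------------------------------------------------------------------
# Role assignment
# ---------------------------------------------------------------------------

def assign_roles(
    system: MolecularSystem, roles: ChemistryRoles | None = None
) -> MolecularSystem:
    """Tag every atom with its chemistry roles.

    Pure function of residue and atom names.  Atoms of residues missing from
    the role tables stay role-free (a warning is logged once per residue
    name).  Side chains only: terminal amine/carboxylate atoms are not part
    of the shipped tables.
    """
    if roles is None:
        roles = ChemistryRoles.default()
    tag_map: dict[int, set[str]] = {i: set() for i in range(system.n_atoms)}
    warned: set[str] = set()
    for i, atom in enumerate(system.atoms):
        res = atom.residue_name
        if (
            res not in roles.hbond_donors
            and res not in roles.hbond_acceptors
            and res not in roles.acidic_oxygens
            and res not in roles.basic_nitrogens
        ):
            if res not in warned:
                logger.warning("no chemistry roles for residue %s; atoms left role-free", res)
                warned.add(res)
            continue
        if atom.name in roles.acidic_oxygens.get(res, ()):
            tag_map[i].add(ROLE_ACIDIC_O)
        if atom.name in roles.basic_nitrogens.get(res, ()):
            tag_map[i].add(ROLE_BASIC_N)
        for heavy, hydrogens in roles.hbond_donors.get(res, ()):
            if atom.name == heavy:
                tag_map[i].add(ROLE_DONOR)
            if atom.name in hydrogens:
                tag_map[i].add(ROLE_DONOR_H)
        for acceptor, antecedent in roles.hbond_acceptors.get(res, ()):
            if atom.name == acceptor:
                tag_map[i].add(ROLE_ACCEPTOR)
            if atom.name == antecedent:
                tag_map[i].add(ROLE_ANTECEDENT)
    new_atoms = [
        dataclasses.replace(a, roles=frozenset(tag_map[i]))
        for i, a in enumerate(system.atoms)
    ]
    return system.with_atoms(new_atoms)
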