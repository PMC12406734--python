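"""Synthetic trajectory ensembles with known ground truth.

Real interaction-network inputs are microsecond MD ensembles that cannot be
regenerated at desk scale, so every analysis stage here is exercised on
designed trajectories instead: an idealized extended peptide provides the
topology (template-complete atoms, explicit donor hydrogens); per-frame
isotropic Gaussian jitter provides harmonic positional fluctuation with
known per-atom variance; and each designed contact follows a two-state
Markov chain whose stationary occupancy equals its target, with the contact
atoms placed at a bound geometry (inside all criteria by >= 0.3 A margin)
or an unbound geometry (outside them by the same margin) according to the
state.  Contact-group atoms are exempt from jitter so a frame's detected
state equals the chain's state exactly; an optional random rigid motion per
frame exercises superposition.  Everything is deterministic under a fixed
seed (NumPy PCG64 streams derived from the seed).

The geometry is idealized, not physically minimized: analysis code must not
assume realistic stereochemistry beyond template bonding.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .fluctuation import TrimPolicy
from .interactions import HBOND, SALTBRIDGE, InteractionCriteria
from .structure_io import (
    ROLE_ACIDIC_O,
    ROLE_BASIC_N,
    Atom,
    ChemistryRoles,
    Ensemble,
    MolecularSystem,
    Trajectory,
    assign_roles,
    load_residue_templates,
    template_bonds,
    write_multimodel_pdb,
)

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

_RESIDUE_SPACING = 3.8  # A between consecutive backbone N atoms
_HEAVY_BOND = 1.45
_H_BOND = 1.0

def _fibonacci_sphere(n: int = 64) -> np.ndarray:
    """Deterministic, roughly uniform unit directions (golden-spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5 ** 0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.cos(phi), np.sin(phi) * np.sin(theta)],
        axis=1,
    )

_ALL_DIRS = _fibonacci_sphere()
# side chains must keep growing away from the backbone (+y) so residues in
# neighbouring columns never interleave; hydrogens may point anywhere
_HEAVY_DIRS = _ALL_DIRS[_ALL_DIRS[:, 1] > 0.45]


def _best_direction(
    parent_pos: np.ndarray,
    length: float,
    candidates: np.ndarray,
    occupied: list[np.ndarray],
) -> np.ndarray:
    """Candidate position maximizing the clearance to already-placed atoms."""
    positions = parent_pos[None] + candidates * length
    occ = [p for p in occupied if np.linalg.norm(p - parent_pos) > 1e-9]
    if not occ:
        return positions[0]
    occ = np.asarray(occ)
    clearance = np.linalg.norm(
        positions[:, None, :] - occ[None], axis=-1
    ).min(axis=1)
    return positions[int(np.argmax(clearance))]


@dataclass(frozen=True)
class ContactSpec:
    """A designed interaction with per-system target occupancy.

    ``residue_a`` is the acidic (salt bridge) or acceptor-side (H-bond)
    residue number, ``residue_b`` the basic or donor-side one.
    ``occupancy`` maps system label to target occupancy (a plain float
    applies to every system).  ``mean_dwell_frames`` is the expected bound-
    state dwell, giving MD-like autocorrelation.
    """

    name: str
    kind: str  # "hbond" | "saltbridge"
    residue_a: int
    residue_b: int
    occupancy: dict[str, float] | float
    bound_distance: float | None = None
    unbound_distance: float = 6.5
    mean_dwell_frames: float = 20.0

    def target_for(self, label: str) -> float:
        if isinstance(self.occupancy, dict):
            return float(self.occupancy[label])
        return float(self.occupancy)


@dataclass
class EnsembleSpec:
    """Design of a synthetic multi-system, multi-replicate ensemble.

    Defaults mirror the conventional simulation design this pipeline
    analyses: 3 replicates per system and 10 ps between saved frames.
    """

    sequence: str
    system_labels: list[str]
    reference_label: str
    contacts: list[ContactSpec] = field(default_factory=list)
    replicates: int = 3
    n_frames: int = 1000
    frame_interval_ps: float = 10.0
    jitter_sigma: float = 0.3
    rigid_motion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reference_label not in self.system_labels:
            raise ValueError("reference_label must be among system_labels")
        if self.n_frames < 2 or self.replicates < 1:
            raise ValueError("need n_frames >= 2 and replicates >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")


# ---------------------------------------------------------------------------
# Peptide builder
# ---------------------------------------------------------------------------

def make_peptide_system(
    sequence: str,
    label: str = "SYN",
    chain_id: str = "A",
    seed: int = 0,
) -> tuple[MolecularSystem, np.ndarray]:
    """Idealized extended-chain peptide with template-complete atoms.

    Backbone atoms lie along x (one residue every 3.8 A); side chains grow
    along +y following the residue template tree.  Fully deterministic
    (``seed`` is accepted for interface symmetry but the construction is
    seed-independent).  Raises ``KeyError`` for unknown residue codes.
    """
    del seed
    templates = load_residue_templates()
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    for i, letter in enumerate(sequence):
        try:
            resname = _ONE_TO_THREE[letter.upper()]
        except KeyError:
            raise KeyError(f"unknown residue code {letter!r} in sequence") from None
        resnum = i + 1
        x = i * _RESIDUE_SPACING
        backbone = {
            "N": np.array([x, 0.0, 0.0]),
            "H": np.array([x, -0.55, 0.84]),
            "CA": np.array([x + 1.2, 0.9, 0.0]),
            "C": np.array([x + 2.5, 0.2, 0.0]),
            "O": np.array([x + 2.5, -1.15, 0.0]),
        }
        placed: dict[str, np.ndarray] = {}
        # clearance targets: this residue so far plus the neighbouring
        # backbone carbonyl/amide atoms
        occupied: list[np.ndarray] = [
            backbone["C"] + np.array([_RESIDUE_SPACING, 0, 0]),
            backbone["O"] + np.array([_RESIDUE_SPACING, 0, 0]),
            backbone["N"] - np.array([_RESIDUE_SPACING, 0, 0]),
        ]
        for name, element, parent in templates[resname]:
            if name in backbone:
                pos = backbone[name]
            else:
                ppos = placed[parent]
                if element == "H":
                    pos = _best_direction(ppos, _H_BOND, _ALL_DIRS, occupied)
                else:
                    pos = _best_direction(ppos, _HEAVY_BOND, _HEAVY_DIRS, occupied)
            placed[name] = pos
            occupied.append(pos)
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element=element,
                    residue_name=resname,
                    residue_number=resnum,
                    chain_id=chain_id,
                    is_hydrogen=element == "H",
                )
            )
            coords.append(pos)
            serial += 1
    system = MolecularSystem(atoms=tuple(atoms), label=label)
    system = dataclasses.replace(system, bonds=template_bonds(system))
    return assign_roles(system), np.array(coords)


# ---------------------------------------------------------------------------
# Contact placement
# ---------------------------------------------------------------------------

@dataclass
class _Placement:
    """Resolved geometry for one contact: state-dependent atom positions."""

    contact: ContactSpec
    mobile: list[int]
    bound: np.ndarray  # (len(mobile), 3)
    unbound: np.ndarray
    fixed: list[int]  # atoms pinned to reference (jitter-exempt, not moved)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length direction in contact placement")
    return v / n


def _group_com(ref: np.ndarray, system: MolecularSystem, idx: list[int]) -> np.ndarray:
    m = np.array([system.atoms[i].mass for i in idx])
    return (ref[idx] * m[:, None]).sum(axis=0) / m.sum()


def _resolve_contact(
    contact: ContactSpec,
    system: MolecularSystem,
    ref: np.ndarray,
    criteria: InteractionCriteria,
    chain_id: str = "A",
) -> _Placement:
    margin = 0.3
    if contact.kind == SALTBRIDGE:
        bound_d = contact.bound_distance or 2.6
        acidic = [
            i for i, a in enumerate(system.atoms)
            if a.residue_number == contact.residue_a and ROLE_ACIDIC_O in a.roles
        ]
        basic = [
            i for i, a in enumerate(system.atoms)
            if a.residue_number == contact.residue_b and ROLE_BASIC_N in a.roles
        ]
        if not acidic or not basic:
            raise ValueError(
                f"contact {contact.name}: residues {contact.residue_a}/"
                f"{contact.residue_b} lack acidic/basic side-chain groups"
            )
        hydrogens = [
            j for i in basic for j in system.bonded_to(i)
            if system.atoms[j].is_hydrogen
        ]
        mobile = sorted(set(basic) | set(hydrogens))
        acid_com = _group_com(ref, system, acidic)
        basic_com = _group_com(ref, system, basic)
        u = _unit(basic_com - acid_com)
        shift_bound = acid_com + u * bound_d - basic_com
        bound = ref[mobile] + shift_bound
        unbound = ref[mobile] + (acid_com + u * contact.unbound_distance - basic_com)
        # verify the designed margins on the actual geometry
        bmap = dict(zip(mobile, bound))
        bpos = np.array([bmap[i] for i in basic])
        d_on = np.linalg.norm(ref[acidic][:, None] - bpos[None], axis=-1)
        if d_on.min() > criteria.sb_candidate_max - margin:
            raise ValueError(
                f"contact {contact.name}: bound O-N distance {d_on.min():.2f} A "
                f"misses the candidate cutoff by < {margin} A margin"
            )
        if bound_d > criteria.sb_occupancy_max - margin:
            raise ValueError(
                f"contact {contact.name}: bound COM distance {bound_d:.2f} A "
                f"too close to the occupancy cutoff"
            )
        if contact.unbound_distance < criteria.sb_occupancy_max + margin:
            raise ValueError(f"contact {contact.name}: unbound distance too small")
        return _Placement(
            contact=contact, mobile=mobile, bound=bound, unbound=unbound,
            fixed=sorted(acidic),
        )
    if contact.kind == HBOND:
        bound_d = contact.bound_distance or 2.9
        if bound_d > criteria.hb_da_max - margin:
            raise ValueError(f"contact {contact.name}: bound D-A distance too large")
        if contact.unbound_distance < criteria.hb_da_max + margin:
            raise ValueError(f"contact {contact.name}: unbound distance too small")
        # donor side: backbone amide of residue_b; acceptor side: side-chain
        # carboxylate OD1/OE1 (antecedent CG/CD) of residue_a if present,
        # otherwise its backbone carbonyl O (antecedent C).
        def _idx(resnum: int, name: str) -> int | None:
            try:
                return system.atom_index(chain_id, resnum, name)
            except KeyError:
                return None

        d_i = _idx(contact.residue_b, "N")
        h_i = _idx(contact.residue_b, "H")
        if d_i is None or h_i is None:
            raise ValueError(
                f"contact {contact.name}: residue {contact.residue_b} has no "
                "backbone amide donor"
            )
        a_i = aa_i = None
        for acc, ant in (("OD1", "CG"), ("OE1", "CD"), ("O", "C")):
            a_i, aa_i = _idx(contact.residue_a, acc), _idx(contact.residue_a, ant)
            if a_i is not None and aa_i is not None:
                break
        if a_i is None or aa_i is None:
            raise ValueError(
                f"contact {contact.name}: residue {contact.residue_a} has no acceptor"
            )
        d_pos = ref[d_i]
        # point the D-H...A axis mostly out of the backbone plane (+z) so the
        # placed hydrogen/acceptor cannot collide with chain neighbours
        v_xy = ref[a_i] - d_pos
        v_xy[2] = 0.0
        tilt = 0.25 * _unit(v_xy) if np.linalg.norm(v_xy) > 1e-9 else 0.0
        u = _unit(np.array([0.0, 0.0, 1.0]) + tilt)
        p = _unit(np.cross(u, [0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.cross(u, [1.0, 0.0, 0.0]))
        h_pos = d_pos + u * _H_BOND
        a_bound = d_pos + u * bound_d
        aa_bound = a_bound + (u * 0.5 + p * np.sqrt(0.75)) * 1.4  # 120 deg off the D-A axis
        shift = u * (contact.unbound_distance - bound_d)
        mobile = [h_i, a_i, aa_i]
        bound = np.array([h_pos, a_bound, aa_bound])
        unbound = np.array([h_pos, a_bound + shift, aa_bound + shift])
        return _Placement(
            contact=contact, mobile=mobile, bound=bound, unbound=unbound,
            fixed=[d_i],
        )
    raise ValueError(f"unknown contact kind {contact.kind!r}")


def _check_clashes(
    system: MolecularSystem,
    ref: np.ndarray,
    placements: list[_Placement],
    min_dist: float = 1.0,
) -> None:
    """Reject designed geometries that put a contact atom < 1 A from a
    non-bonded atom in either state."""
    for pl in placements:
        for state_coords in (pl.bound, pl.unbound):
            for local, i in enumerate(pl.mobile):
                pos = state_coords[local]
                d = np.linalg.norm(ref - pos, axis=1)
                bonded = set(system.bonded_to(i)) | {i} | set(pl.mobile)
                for j in np.nonzero(d < min_dist)[0]:
                    if int(j) not in bonded:
                        raise ValueError(
                            f"contact {pl.contact.name}: atom "
                            f"{system.atoms[i].label()} clashes with "
                            f"{system.atoms[int(j)].label()} "
                            f"({d[int(j)]:.2f} A < {min_dist} A)"
                        )


# ---------------------------------------------------------------------------
# Markov switching
# ---------------------------------------------------------------------------

def markov_rates(occupancy: float, mean_dwell_frames: float) -> tuple[float, float]:
    """Per-frame (bound->unbound, unbound->bound) switch probabilities with
    stationary bound probability ``occupancy``."""
    p = float(occupancy)
    if p <= 0.0:
        return 1.0, 0.0
    if p >= 1.0:
        return 0.0, 1.0
    a = min(1.0, 1.0 / mean_dwell_frames)
    b = a * p / (1.0 - p)
    if b > 1.0:
        b = 1.0
        a = b * (1.0 - p) / p
    return a, b


def simulate_markov_states(
    occupancy: float,
    mean_dwell_frames: float,
    n_frames: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-state chain (1 = bound) started from its stationary distribution."""
    a, b = markov_rates(occupancy, mean_dwell_frames)
    states = np.empty(n_frames, dtype=bool)
    u = rng.random(n_frames)
    states[0] = u[0] < occupancy
    for t in range(1, n_frames):
        states[t] = (not states[t - 1] and u[t] < b) or (states[t - 1] and u[t] >= a)
    return states


def effective_sample_size(n_frames: int, occupancy: float, mean_dwell_frames: float) -> float:
    """Autocorrelation-corrected frame count for occupancy-error bounds.

    For a two-state chain with switch probabilities a, b the variance of the
    occupancy estimate is p(1-p)/n * (1+l)/(1-l) with l = 1-a-b, so
    n_eff = n (1-l)/(1+l).
    """
    a, b = markov_rates(occupancy, mean_dwell_frames)
    lam = max(min(1.0 - a - b, 1.0 - 1e-9), -(1.0 - 1e-9))
    return n_frames * (1.0 - lam) / (1.0 + lam)


def occupancy_standard_error(
    occupancy: float, n_frames: int, mean_dwell_frames: float
) -> float:
    p = min(max(occupancy, 1e-12), 1 - 1e-12)
    n_eff = effective_sample_size(n_frames, occupancy, mean_dwell_frames)
    return float(np.sqrt(p * (1 - p) / n_eff))


# ---------------------------------------------------------------------------
# Ensemble simulation
# ---------------------------------------------------------------------------

def simulate_ensemble(
    spec: EnsembleSpec,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> tuple[Ensemble, pd.DataFrame]:
    """Generate the ensemble and its ground-truth record.

    Returns ``(ensemble, ground_truth)`` where the ground truth has one row
    per (contact, system, replicate) with the target and the realized
    frame-count occupancy (over all frames and after the default 10 % trim),
    plus one ``jitter_sigma`` row per system.
    """
    system, ref = make_peptide_system(spec.sequence)
    placements = [_resolve_contact(c, system, ref, criteria) for c in spec.contacts]
    _check_clashes(system, ref, placements)
    pinned = sorted({i for pl in placements for i in pl.mobile + pl.fixed})
    trim = TrimPolicy(0.10)
    first_kept = trim.first_retained(spec.n_frames) if spec.n_frames >= 3 else 0

    systems: dict[str, list[Trajectory]] = {}
    rows: list[dict] = []
    for si, label in enumerate(spec.system_labels):
        reps: list[Trajectory] = []
        for ri in range(spec.replicates):
            rng = np.random.default_rng([spec.seed, si, ri])
            coords = ref[None] + rng.normal(
                0.0, spec.jitter_sigma, size=(spec.n_frames, system.n_atoms, 3)
            )
            if pinned:
                coords[:, pinned] = ref[pinned]
            for pl in placements:
                target = pl.contact.target_for(label)
                states = simulate_markov_states(
                    target, pl.contact.mean_dwell_frames, spec.n_frames, rng
                )
                coords[:, pl.mobile] = np.where(
                    states[:, None, None], pl.bound[None], pl.unbound[None]
                )
                realized = float(states.mean())
                realized_trimmed = float(states[first_kept:].mean())
                rows.append(
                    {
                        "record": "contact",
                        "contact": pl.contact.name,
                        "kind": pl.contact.kind,
                        "system": label,
                        "replicate": ri + 1,
                        "target_occupancy": target,
                        "realized_occupancy": realized,
                        "realized_occupancy_trimmed": realized_trimmed,
                        "n_frames": spec.n_frames,
                        "mean_dwell_frames": pl.contact.mean_dwell_frames,
                    }
                )
            if spec.rigid_motion:
                rot = Rotation.random(spec.n_frames, rng=rng).as_matrix()
                shift = rng.uniform(-20.0, 20.0, size=(spec.n_frames, 1, 3))
                coords = np.einsum("fij,fnj->fni", rot, coords) + shift
            reps.append(
                Trajectory(
                    system=system,
                    coordinates=coords,
                    frame_interval_ps=spec.frame_interval_ps,
                    replicate_id=ri + 1,
                )
            )
        rows.append(
            {
                "record": "sigma",
                "contact": "",
                "kind": "",
                "system": label,
                "replicate": 0,
                "target_occupancy": np.nan,
                "realized_occupancy": np.nan,
                "realized_occupancy_trimmed": np.nan,
                "n_frames": spec.n_frames,
                "mean_dwell_frames": np.nan,
                "jitter_sigma": spec.jitter_sigma,
            }
        )
        systems[label] = reps
    ensemble = Ensemble(systems=systems, reference_label=spec.reference_label)
    return ensemble, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The designed reference-vs-variants fixture
# ---------------------------------------------------------------------------

#: 33-residue host sequence: alanine scaffold with charged/glycine residues
#: at the designed contact positions.
_FIXTURE_SEQUENCE = list("A" * 33)
for _pos, _aa in [(2, "K"), (7, "D"), (10, "K"), (13, "D"), (16, "D"),
                  (19, "K"), (22, "D"), (25, "G"), (28, "K"), (31, "D")]:
    _FIXTURE_SEQUENCE[_pos - 1] = _aa
FIXTURE_SEQUENCE = "".join(_FIXTURE_SEQUENCE)

#: Designed contacts of the reference-vs-variants fixture: one strong salt
#: bridge lost in every variant, a motif triplet (2 salt bridges + 1 H-bond)
#: retained in two variants and ablated in the third, and a sub-threshold
#: distractor.
FIXTURE_CONTACTS = [
    ContactSpec(
        name="bridge_K2-D7", kind=SALTBRIDGE, residue_a=7, residue_b=2,
        occupancy={"WT": 0.85, "M1": 0.05, "M2": 0.05, "M3": 0.05},
    ),
    ContactSpec(
        name="motif_sb_K10-D13", kind=SALTBRIDGE, residue_a=13, residue_b=10,
        occupancy={"WT": 0.80, "M1": 0.75, "M2": 0.70, "M3": 0.05},
    ),
    ContactSpec(
        name="motif_sb_D16-K19", kind=SALTBRIDGE, residue_a=16, residue_b=19,
        occupancy={"WT": 0.80, "M1": 0.70, "M2": 0.75, "M3": 0.05},
    ),
    ContactSpec(
        name="motif_hb_D22-G25", kind=HBOND, residue_a=22, residue_b=25,
        occupancy={"WT": 0.75, "M1": 0.70, "M2": 0.72, "M3": 0.05},
    ),
    ContactSpec(
        name="distractor_K28-D31", kind=SALTBRIDGE, residue_a=31, residue_b=28,
        occupancy=0.20,
    ),
]


def make_reference_variant_fixture(
    seed: int = 0,
    n_frames: int = 2000,
    replicates: int = 3,
    jitter_sigma: float = 0.25,
    rigid_motion: bool = False,
) -> tuple[Ensemble, pd.DataFrame]:
    """Reference + 3 variants, 3 replicates each, with designed contacts.

    The designed pattern: the ``bridge`` salt bridge is high-occupancy in
    the reference and lost in all three variants; the ``motif`` triplet
    (two salt bridges and one H-bond) is retained in M1 and M2 and ablated
    in M3; the ``distractor`` stays below every reporting threshold.

    The default length is set so the max-over-replicates estimate of the
    20 % distractor stays below the 40 % filter with a ~4-sigma margin
    under the dwell-corrected sampling error (mean dwell 20 frames).
    """
    spec = EnsembleSpec(
        sequence=FIXTURE_SEQUENCE,
        system_labels=["WT", "M1", "M2", "M3"],
        reference_label="WT",
        contacts=FIXTURE_CONTACTS,
        replicates=replicates,
        n_frames=n_frames,
        jitter_sigma=jitter_sigma,
        rigid_motion=rigid_motion,
        seed=seed,
    )
    return simulate_ensemble(spec)


def write_fixture(
    ensemble: Ensemble,
    ground_truth: pd.DataFrame,
    directory: str | Path,
) -> dict[str, list[Path]]:
    """Write one multi-model PDB per replicate plus the ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[Path]] = {}
    for label, reps in ensemble.systems.items():
        paths = []
        for t in reps:
            p = directory / f"{label}_rep{t.replicate_id}.pdb"
            write_multimodel_pdb(t, p)
            paths.append(p)
        manifest[label] = paths
    ground_truth.to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    return manifest
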