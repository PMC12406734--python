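"""Per-frame hydrogen-bond and salt-bridge detection and occupancy statistics.

Hydrogen bonds follow HBPLUS-style geometric criteria: D-A <= 3.9 A,
H-A <= 2.5 A and all three of the D-H-A, H-A-AA and D-A-AA angles >= 90
degrees (AA = acceptor antecedent, the heavy atom bonded to the acceptor).
All five tests must pass in a frame for the bond to count in that frame.

Salt bridges use a two-stage scheme: a residue pair (acidic Asp/Glu vs basic
Lys/Arg side chain) is a *candidate* if any single acidic oxygen comes
within 3.2 A of any single basic nitrogen in at least one retained frame;
the *occupancy* of a candidate is the fraction of retained frames in which
the mass-weighted centers of the two charged groups are within 3.5 A.

Strength/occupancy is the fraction of retained (post-trim) frames in which
the interaction is present, computed per replicate; the value assigned to a
pair is the maximum across replicates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fluctuation import TrimPolicy
from .structure_io import (
    ROLE_ACCEPTOR,
    ROLE_ACIDIC_O,
    ROLE_ANTECEDENT,
    ROLE_BASIC_N,
    ROLE_DONOR,
    ROLE_DONOR_H,
    Atom,
    MolecularSystem,
    Trajectory,
    assign_roles,
)

#: Numerical slack on inclusive distance (A) and angle (degrees) thresholds,
#: so that geometries constructed exactly at a printed cutoff are inside it.
GEOM_EPS = 1e-9

HBOND = "hbond"
SALTBRIDGE = "saltbridge"


@dataclass(frozen=True)
class InteractionCriteria:
    """Geometric cutoffs and reporting thresholds.

    Distances in Angstrom, angles in degrees; ``sb_report_min`` and
    ``hb_variation_min`` are fractions of simulation time (0.40 = 40 %).
    The salt-bridge reporting filter is strict (> 0.40); every geometric
    comparison is inclusive, exactly as conventionally stated.
    """

    hb_da_max: float = 3.9
    hb_ha_max: float = 2.5
    hb_angle_min: float = 90.0
    sb_candidate_max: float = 3.2
    sb_occupancy_max: float = 3.5
    sb_report_min: float = 0.40
    hb_variation_min: float = 0.40

    def __post_init__(self) -> None:
        for name in ("hb_da_max", "hb_ha_max", "sb_candidate_max", "sb_occupancy_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.hb_angle_min < 180.0):
            raise ValueError("hb_angle_min must be in (0, 180)")
        for name in ("sb_report_min", "hb_variation_min"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")


@dataclass(frozen=True)
class HBondCandidate:
    """One (donor heavy, hydrogen, acceptor, antecedent) triple, as indices."""

    donor: int
    hydrogen: int
    acceptor: int
    antecedent: int
    donor_atom: Atom
    hydrogen_atom: Atom
    acceptor_atom: Atom

    @property
    def key(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        """(donor, acceptor) atom identity, residue-name independent."""
        d, a = self.donor_atom, self.acceptor_atom
        return (
            (d.chain_id, d.residue_number, d.name),
            (a.chain_id, a.residue_number, a.name),
        )


@dataclass(frozen=True)
class SaltBridgePair:
    """An acidic/basic side-chain residue pair with its charged-group atoms."""

    acidic_residue: tuple[str, int, str]
    basic_residue: tuple[str, int, str]
    acidic_group: tuple[int, ...]
    basic_group: tuple[int, ...]

    @property
    def key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (
            (self.acidic_residue[0], self.acidic_residue[1]),
            (self.basic_residue[0], self.basic_residue[1]),
        )


@dataclass(frozen=True)
class PairStatistic:
    """Per-replicate and max-aggregated strength of one interaction."""

    key: str
    kind: str
    per_replicate_strength: tuple[float, ...]
    endpoints: tuple[tuple[str, int, str], tuple[str, int, str]]
    match_key: tuple = field(default=())

    @property
    def aggregated_strength(self) -> float:
        return max(self.per_replicate_strength)


def _one_letter(resname: str) -> str:
    table = {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }
    return table.get(resname, "X")


def residue_tag(residue: tuple[str, int, str]) -> str:
    """Compact residue label in the K193 style (one-letter code + number)."""
    chain, number, name = residue
    return f"{_one_letter(name)}{number}"


def ensure_roles(system: MolecularSystem) -> MolecularSystem:
    """Annotate with default chemistry roles unless roles are already set."""
    if any(a.roles for a in system.atoms):
        return system
    return assign_roles(system)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def enumerate_hbond_candidates(system: MolecularSystem) -> list[HBondCandidate]:
    """All (donor-H, acceptor) combinations, excluding same-residue pairs.

    Requires role annotation and explicit donor hydrogens: a tagged donor
    heavy atom with no bonded donor hydrogen raises ``ValueError`` (silent
    hydrogen placement is never attempted).
    """
    system = ensure_roles(system)
    atoms = system.atoms
    donors: list[tuple[int, list[int]]] = []
    for i, a in enumerate(atoms):
        if ROLE_DONOR in a.roles:
            hs = [
                j for j in system.bonded_to(i)
                if ROLE_DONOR_H in atoms[j].roles
                and atoms[j].residue_key == a.residue_key
            ]
            if not hs:
                raise ValueError(
                    f"donor {a.label()} has no attached hydrogen in the "
                    "coordinates; explicit hydrogens are required"
                )
            donors.append((i, hs))
    acceptors: list[tuple[int, int]] = []
    for i, a in enumerate(atoms):
        if ROLE_ACCEPTOR in a.roles:
            antecedents = [
                j for j in system.bonded_to(i)
                if ROLE_ANTECEDENT in atoms[j].roles
                and atoms[j].residue_key == a.residue_key
            ]
            if len(antecedents) != 1:
                raise ValueError(
                    f"acceptor {a.label()} has {len(antecedents)} antecedent "
                    "candidates; exactly one is required"
                )
            acceptors.append((i, antecedents[0]))
    out: list[HBondCandidate] = []
    for (d, hs), (acc, aa) in itertools.product(donors, acceptors):
        if atoms[d].residue_key == atoms[acc].residue_key:
            continue
        if d == acc:
            continue
        for h in hs:
            out.append(
                HBondCandidate(
                    donor=d, hydrogen=h, acceptor=acc, antecedent=aa,
                    donor_atom=atoms[d], hydrogen_atom=atoms[h],
                    acceptor_atom=atoms[acc],
                )
            )
    return out


def _angles_deg(a: np.ndarray, apex: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Angle at ``apex`` between ``a`` and ``b`` (degrees), batched (..., 3)."""
    v1 = a - apex
    v2 = b - apex
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.einsum("...i,...i->...", v1, v2) / np.maximum(n1 * n2, 1e-30)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def hbond_presence_matrix(
    coordinates: np.ndarray,
    candidates: list[HBondCandidate],
    criteria: InteractionCriteria = InteractionCriteria(),
) -> np.ndarray:
    """Boolean ``(n_frames, n_candidates)`` presence matrix.

    A candidate is present in a frame iff all five tests pass:
    |D-A| <= hb_da_max, |H-A| <= hb_ha_max, and the D-H-A, H-A-AA and
    D-A-AA angles are all >= hb_angle_min.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if not candidates:
        return np.zeros((coords.shape[0], 0), dtype=bool)
    d = coords[:, [c.donor for c in candidates]]
    h = coords[:, [c.hydrogen for c in candidates]]
    a = coords[:, [c.acceptor for c in candidates]]
    aa = coords[:, [c.antecedent for c in candidates]]
    da = np.linalg.norm(d - a, axis=-1)
    ha = np.linalg.norm(h - a, axis=-1)
    ang_dha = _angles_deg(d, h, a)
    ang_haaa = _angles_deg(h, a, aa)
    ang_daaa = _angles_deg(d, a, aa)
    amin = criteria.hb_angle_min - GEOM_EPS
    return (
        (da <= criteria.hb_da_max + GEOM_EPS)
        & (ha <= criteria.hb_ha_max + GEOM_EPS)
        & (ang_dha >= amin)
        & (ang_haaa >= amin)
        & (ang_daaa >= amin)
    )


def hbond_present(
    frame_coordinates: np.ndarray,
    candidate: HBondCandidate,
    criteria: InteractionCriteria = InteractionCriteria(),
) -> bool:
    """Single-frame, single-candidate convenience wrapper."""
    return bool(hbond_presence_matrix(frame_coordinates, [candidate], criteria)[0, 0])


def _hbond_key_label(key) -> str:
    (dc, dn, da_), (ac, an, aa_) = key
    return f"{dc}:{dn}:{da_}->{ac}:{an}:{aa_}"


def hbond_statistics(
    replicates: list[Trajectory],
    criteria: InteractionCriteria = InteractionCriteria(),
    trim: TrimPolicy = TrimPolicy(0.10),
) -> list[PairStatistic]:
    """Atom-level (donor, acceptor) H-bond strengths, max-aggregated.

    Presence of a (D, A) key in a frame means *any* hydrogen of that donor
    satisfies the criteria against that acceptor.
    """
    if not replicates:
        raise ValueError("at least one replicate is required")
    system = ensure_roles(replicates[0].system)
    candidates = enumerate_hbond_candidates(system)
    keys = sorted({c.key for c in candidates})
    key_cols: dict[tuple, list[int]] = {k: [] for k in keys}
    for j, c in enumerate(candidates):
        key_cols[c.key].append(j)
    per_key: dict[tuple, list[float]] = {k: [] for k in keys}
    for traj in replicates:
        retained = trim.retained_indices(traj.n_frames)
        presence = hbond_presence_matrix(
            traj.coordinates[retained], candidates, criteria
        )
        for k in keys:
            any_h = presence[:, key_cols[k]].any(axis=1)
            per_key[k].append(float(any_h.mean()))
    atoms = system.atoms
    stats = []
    for k in keys:
        d_idx = system.atom_index(*k[0])
        a_idx = system.atom_index(*k[1])
        d, a = atoms[d_idx], atoms[a_idx]
        stats.append(
            PairStatistic(
                key=f"{d.label()}->{a.label()}",
                kind=HBOND,
                per_replicate_strength=tuple(per_key[k]),
                endpoints=(
                    (d.chain_id, d.residue_number, d.residue_name),
                    (a.chain_id, a.residue_number, a.residue_name),
                ),
                match_key=k,
            )
        )
    return stats


def hbond_strength(
    replicates: list[Trajectory],
    key: tuple[tuple[str, int, str], tuple[str, int, str]],
    criteria: InteractionCriteria = InteractionCriteria(),
    trim: TrimPolicy = TrimPolicy(0.10),
) -> PairStatistic:
    """Strength of one (donor atom, acceptor atom) key across replicates."""
    for stat in hbond_statistics(replicates, criteria, trim):
        if stat.match_key == key:
            return stat
    raise KeyError(f"no H-bond candidate with key {key}")


def hbond_residue_statistics(atom_stats: list[PairStatistic]) -> list[PairStatistic]:
    """Residue-pair roll-up: element-wise max over the pair's atom keys."""
    grouped: dict[tuple, list[PairStatistic]] = {}
    for s in atom_stats:
        (dc, dn, _), (ac, an, _) = s.match_key
        grouped.setdefault(((dc, dn), (ac, an)), []).append(s)
    out = []
    for rkey, members in sorted(grouped.items()):
        strengths = np.max(
            [m.per_replicate_strength for m in members], axis=0
        )
        e0, e1 = members[0].endpoints
        out.append(
            PairStatistic(
                key=f"{residue_tag(e0)}-{residue_tag(e1)}",
                kind=HBOND,
                per_replicate_strength=tuple(float(x) for x in strengths),
                endpoints=(e0, e1),
                match_key=rkey,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

def salt_bridge_pairs(system: MolecularSystem) -> list[SaltBridgePair]:
    """Every acidic-residue / basic-residue pairing with charged-group atoms."""
    system = ensure_roles(system)
    acidic: dict[tuple[str, int, str], list[int]] = {}
    basic: dict[tuple[str, int, str], list[int]] = {}
    for i, a in enumerate(system.atoms):
        rid = (a.chain_id, a.residue_number, a.residue_name)
        if ROLE_ACIDIC_O in a.roles:
            acidic.setdefault(rid, []).append(i)
        if ROLE_BASIC_N in a.roles:
            basic.setdefault(rid, []).append(i)
    out = []
    for ar, agroup in sorted(acidic.items()):
        for br, bgroup in sorted(basic.items()):
            if (ar[0], ar[1]) == (br[0], br[1]):
                continue
            out.append(
                SaltBridgePair(
                    acidic_residue=ar, basic_residue=br,
                    acidic_group=tuple(agroup), basic_group=tuple(bgroup),
                )
            )
    return out


def _min_on_distance(coords: np.ndarray, pair: SaltBridgePair) -> np.ndarray:
    """Per-frame minimum acidic-O to basic-N atomic distance."""
    o = coords[:, pair.acidic_group]  # (F, nO, 3)
    n = coords[:, pair.basic_group]  # (F, nN, 3)
    diff = o[:, :, None, :] - n[:, None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1)).min(axis=(1, 2))


def _com_distance(coords: np.ndarray, pair: SaltBridgePair, system: MolecularSystem) -> np.ndarray:
    """Per-frame mass-weighted charged-group center-of-mass distance."""
    mo = np.array([system.atoms[i].mass for i in pair.acidic_group])
    mn = np.array([system.atoms[i].mass for i in pair.basic_group])
    com_o = (coords[:, pair.acidic_group] * mo[None, :, None]).sum(axis=1) / mo.sum()
    com_n = (coords[:, pair.basic_group] * mn[None, :, None]).sum(axis=1) / mn.sum()
    return np.linalg.norm(com_o - com_n, axis=-1)


def salt_bridge_candidates(
    replicates: list[Trajectory],
    criteria: InteractionCriteria = InteractionCriteria(),
    trim: TrimPolicy = TrimPolicy(0.10),
) -> list[SaltBridgePair]:
    """Pairs whose minimum O-N distance is <= sb_candidate_max in >= 1 retained frame."""
    if not replicates:
        raise ValueError("at least one replicate is required")
    system = ensure_roles(replicates[0].system)
    out = []
    for pair in salt_bridge_pairs(system):
        hit = False
        for traj in replicates:
            retained = trim.retained_indices(traj.n_frames)
            dmin = _min_on_distance(traj.coordinates[retained], pair)
            if (dmin <= criteria.sb_candidate_max + GEOM_EPS).any():
                hit = True
                break
        if hit:
            out.append(pair)
    return out


def salt_bridge_occupancy(
    replicates: list[Trajectory],
    pair: SaltBridgePair,
    criteria: InteractionCriteria = InteractionCriteria(),
    trim: TrimPolicy = TrimPolicy(0.10),
) -> PairStatistic:
    """Fraction of retained frames with group-COM distance <= sb_occupancy_max.

    Computed per replicate; the aggregated value is the maximum across
    replicates.
    """
    system = ensure_roles(replicates[0].system)
    strengths = []
    for traj in replicates:
        retained = trim.retained_indices(traj.n_frames)
        dcom = _com_distance(traj.coordinates[retained], pair, system)
        strengths.append(float((dcom <= criteria.sb_occupancy_max + GEOM_EPS).mean()))
    return PairStatistic(
        key=f"{residue_tag(pair.basic_residue)}-{residue_tag(pair.acidic_residue)}",
        kind=SALTBRIDGE,
        per_replicate_strength=tuple(strengths),
        endpoints=(pair.acidic_residue, pair.basic_residue),
        match_key=pair.key,
    )


def saltbridge_statistics(
    replicates: list[Trajectory],
    criteria: InteractionCriteria = InteractionCriteria(),
    trim: TrimPolicy = TrimPolicy(0.10),
) -> list[PairStatistic]:
    """Occupancy statistics for every candidate salt-bridge pair."""
    return [
        salt_bridge_occupancy(replicates, pair, criteria, trim)
        for pair in salt_bridge_candidates(replicates, criteria, trim)
    ]


# ---------------------------------------------------------------------------
# Tidy output tables
# ---------------------------------------------------------------------------

def statistics_table(stats_by_system: dict[str, list[PairStatistic]]) -> pd.DataFrame:
    """One row per interaction per system, per-replicate and aggregated strengths."""
    rows = []
    for label, stats in stats_by_system.items():
        for s in sorted(stats, key=lambda s: (s.kind, s.key)):
            row = {
                "system": label,
                "kind": s.kind,
                "key": s.key,
                "aggregated_strength": round(s.aggregated_strength, 6),
            }
            for i, v in enumerate(s.per_replicate_strength, start=1):
                row[f"strength_rep{i}"] = round(v, 6)
            rows.append(row)
    return pd.DataFrame(rows)
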