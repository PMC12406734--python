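import numpy as np
import pytest

from mdinet.structure_io import (
    Atom,
    MolecularSystem,
    ROLE_ACCEPTOR,
    ROLE_ACIDIC_O,
    ROLE_ANTECEDENT,
    ROLE_BASIC_N,
    ROLE_DONOR,
    ROLE_DONOR_H,
    Trajectory,
)
from mdinet.synthetic_data import make_peptide_system


@pytest.fixture(scope="session")
def kdag():
    """Small Lys-Asp-Ala-Gly peptide with roles assigned."""
    return make_peptide_system("KDAG")


def minimal_hbond_system():
    """Four atoms (donor N + H, acceptor O + antecedent C), roles hand-set."""
    atoms = (
        Atom(1, "N", "N", "GLY", 1, "A", False,
             roles=frozenset({ROLE_DONOR})),
        Atom(2, "H", "H", "GLY", 1, "A", True,
             roles=frozenset({ROLE_DONOR_H})),
        Atom(3, "O", "O", "GLY", 2, "A", False,
             roles=frozenset({ROLE_ACCEPTOR})),
        Atom(4, "C", "C", "GLY", 2, "A", False,
             roles=frozenset({ROLE_ANTECEDENT})),
    )
    return MolecularSystem(atoms=atoms, bonds=frozenset({(0, 1), (1, 0), (2, 3), (3, 2)}))


def minimal_saltbridge_system():
    """Asp carboxylate oxygens + Lys amine nitrogen, roles hand-set."""
    atoms = (
        Atom(1, "OD1", "O", "ASP", 1, "A", False, roles=frozenset({ROLE_ACIDIC_O})),
        Atom(2, "OD2", "O", "ASP", 1, "A", False, roles=frozenset({ROLE_ACIDIC_O})),
        Atom(3, "NZ", "N", "LYS", 2, "A", False, roles=frozenset({ROLE_BASIC_N})),
    )
    return MolecularSystem(atoms=atoms)


def random_charged_trajectories(seed, max_frames=200, n_replicates=1):
    """Random small peptide trajectories that scatter contact distances
    across the geometric cutoffs (for brute-force oracle comparison)."""
    rng = np.random.default_rng(seed)
    alphabet = "KDEGAS"
    while True:
        n_res = int(rng.integers(3, 6))
        seq = "".join(rng.choice(list(alphabet), size=n_res))
        if seq.count("K") + seq.count("R") == 0:
            continue
        if sum(seq.count(c) for c in "DE") == 0:
            continue
        system, ref = make_peptide_system(seq)
        if system.n_atoms <= 50:
            break
    n_frames = int(rng.integers(20, max_frames + 1))
    reps = []
    for r in range(n_replicates):
        scale = rng.uniform(0.25, 1.0, size=(n_frames, 1, 1))
        center = ref.mean(axis=0)
        coords = (ref - center) * scale + center
        coords += rng.normal(0.0, 0.8, size=coords.shape)
        reps.append(Trajectory(system=system, coordinates=coords, replicate_id=r + 1))
    return reps
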