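"""Rigid-body superposition and backbone RMSD/RMSF with equilibration trimming.

RMSD is computed per frame against the initial frame after optimal proper
superposition over the backbone selection {N, CA, C, O}.  RMSF is computed
per residue about the time-averaged structure via a two-pass procedure:
superpose onto frame 1 and average, then re-superpose onto the mean.  A
TrimPolicy discards a leading fraction of frames (default 0.10, i.e. keeping
the last 90 % of each replicate) from every statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import BACKBONE_SELECTION, Ensemble, Trajectory


@dataclass(frozen=True)
class TrimPolicy:
    """Leading-fraction equilibration trim applied before any statistic.

    ``discard_fraction=0.1`` on a 1,000-frame trajectory retains exactly
    frames 101-1,000 (1-based).
    """

    discard_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.discard_fraction < 1.0):
            raise ValueError("discard_fraction must be in [0, 1)")

    def first_retained(self, n_frames: int) -> int:
        """0-based index of the first retained frame."""
        start = int(np.floor(self.discard_fraction * n_frames))
        if n_frames - start < 2:
            raise ValueError(
                f"trimming {self.discard_fraction:.0%} of {n_frames} frames "
                "leaves fewer than 2"
            )
        return start

    def retained_indices(self, n_frames: int) -> np.ndarray:
        return np.arange(self.first_retained(n_frames), n_frames)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation least-squares fit of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``mobile @ R.T + t`` the superposed
    coordinates.  The rotation is guaranteed proper (det +1, no reflection).

    Raises ``ValueError`` for fewer than 3 points, mismatched shapes, or
    degenerate (collinear/coincident) geometry.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    x = mobile - mc
    y = reference - rc
    h = x.T @ y
    u, s, vt = np.linalg.svd(h)
    scale = max(s[0], 1e-12)
    if s[1] / scale < 1e-8:
        raise ValueError("degenerate geometry: points are collinear or coincident")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = x @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    t = rc - rot @ mc
    return rot, t, rmsd


def _superpose_frames(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Batch-superpose ``(m, n, 3)`` frames onto an ``(n, 3)`` reference."""
    frames = np.asarray(frames, dtype=float)
    ref = reference - reference.mean(axis=0)
    centers = frames.mean(axis=1, keepdims=True)
    x = frames - centers
    h = np.einsum("fni,nj->fij", x, ref)
    u, s, vt = np.linalg.svd(h)
    det = np.sign(np.linalg.det(np.einsum("fij,fjk->fik", vt.transpose(0, 2, 1), u.transpose(0, 2, 1))))
    flip = np.repeat(np.eye(3)[None], len(frames), axis=0)
    flip[:, 2, 2] = det
    rot = np.einsum("fij,fjk,fkl->fil", vt.transpose(0, 2, 1), flip, u.transpose(0, 2, 1))
    fitted = np.einsum("fni,fji->fnj", x, rot) + reference.mean(axis=0)
    return fitted


def _selection_indices(traj: Trajectory, selection: frozenset[str] | set[str]) -> np.ndarray:
    idx = np.array(
        [i for i, a in enumerate(traj.system.atoms) if a.name in selection],
        dtype=int,
    )
    if idx.size < 3:
        raise ValueError(
            f"selection {sorted(selection)} resolves to {idx.size} atoms; need >= 3"
        )
    return idx


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def rmsd_series(
    traj: Trajectory,
    selection: frozenset[str] | set[str] = BACKBONE_SELECTION,
    trim: TrimPolicy = TrimPolicy(0.0),
) -> list[tuple[int, float]]:
    """Per-frame backbone RMSD against the initial frame.

    Every retained frame is superposed onto frame 1 over ``selection`` and
    the RMSD is computed over the same selection.  Returns
    ``[(frame_index, rmsd_A), ...]`` with 0-based frame indices into the
    untrimmed trajectory.
    """
    idx = _selection_indices(traj, selection)
    retained = trim.retained_indices(traj.n_frames)
    ref = traj.coordinates[0, idx]
    frames = traj.coordinates[retained][:, idx]
    fitted = _superpose_frames(frames, ref)
    rmsd = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=2), axis=1))
    return [(int(f), float(r)) for f, r in zip(retained, rmsd)]


def rmsf_profile(
    traj: Trajectory,
    selection: frozenset[str] | set[str] = BACKBONE_SELECTION,
    trim: TrimPolicy = TrimPolicy(0.0),
) -> list[tuple[str, int, str, float]]:
    """Per-residue RMSF about the average structure.

    Two passes: (1) superpose retained frames onto frame 1 over ``selection``
    and form the mean structure; (2) re-superpose retained frames onto that
    mean; per-atom RMSF is the root time-averaged squared displacement from
    the mean, and the per-residue value averages the residue's selected
    atoms.  Returns ``[(chain_id, residue_number, residue_name, rmsf_A), ...]``.
    """
    idx = _selection_indices(traj, selection)
    retained = trim.retained_indices(traj.n_frames)
    frames = traj.coordinates[retained][:, idx]
    pass1 = _superpose_frames(frames, traj.coordinates[0, idx])
    mean_structure = pass1.mean(axis=0)
    pass2 = _superpose_frames(frames, mean_structure)
    mean2 = pass2.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((pass2 - mean2) ** 2, axis=2), axis=0))
    out: list[tuple[str, int, str, float]] = []
    atoms = traj.system.atoms
    by_residue: dict[tuple[str, int, str], list[float]] = {}
    for k, ai in enumerate(idx):
        a = atoms[ai]
        by_residue.setdefault(
            (a.chain_id, a.residue_number, a.residue_name), []
        ).append(per_atom[k])
    for (chain, resnum, resname), values in by_residue.items():
        out.append((chain, resnum, resname, float(np.mean(values))))
    return out


# ---------------------------------------------------------------------------
# Tidy ensemble tables
# ---------------------------------------------------------------------------

def rmsd_table(
    ensemble: Ensemble,
    selection: frozenset[str] | set[str] = BACKBONE_SELECTION,
    trim: TrimPolicy = TrimPolicy(0.10),
) -> pd.DataFrame:
    """rmsd.csv contents: one row per (system, replicate, retained frame)."""
    rows = []
    for label, reps in ensemble.systems.items():
        for t in reps:
            for frame, value in rmsd_series(t, selection, trim):
                rows.append(
                    {
                        "system": label,
                        "replicate": t.replicate_id,
                        "frame": frame,
                        "time_ps": frame * t.frame_interval_ps,
                        "rmsd_A": round(value, 6),
                    }
                )
    return pd.DataFrame(
        rows, columns=["system", "replicate", "frame", "time_ps", "rmsd_A"]
    )


def rmsf_table(
    ensemble: Ensemble,
    selection: frozenset[str] | set[str] = BACKBONE_SELECTION,
    trim: TrimPolicy = TrimPolicy(0.10),
) -> pd.DataFrame:
    """rmsf.csv contents: one row per (system, replicate, residue)."""
    rows = []
    for label, reps in ensemble.systems.items():
        for t in reps:
            for chain, resnum, resname, value in rmsf_profile(t, selection, trim):
                rows.append(
                    {
                        "system": label,
                        "replicate": t.replicate_id,
                        "chain": chain,
                        "residue_number": resnum,
                        "residue_name": resname,
                        "rmsf_A": round(value, 6),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "system", "replicate", "chain", "residue_number", "residue_name", "rmsf_A",
        ],
    )
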