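"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (double loops, scalar math, numerical
optimisation) and shares no code path with the package's vectorized
detection or closed-form superposition.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

EPS = 1e-9


def _dist(p, q) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def _angle_deg(a, apex, b) -> float:
    v1 = [x - y for x, y in zip(a, apex)]
    v2 = [x - y for x, y in zip(b, apex)]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    c = sum(x * y for x, y in zip(v1, v2)) / max(n1 * n2, 1e-30)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def brute_hbond_present(frame, d, h, a, aa, criteria) -> bool:
    """Scalar re-implementation of the five geometric H-bond tests."""
    if _dist(frame[d], frame[a]) > criteria.hb_da_max + EPS:
        return False
    if _dist(frame[h], frame[a]) > criteria.hb_ha_max + EPS:
        return False
    amin = criteria.hb_angle_min - EPS
    if _angle_deg(frame[d], frame[h], frame[a]) < amin:
        return False
    if _angle_deg(frame[h], frame[a], frame[aa]) < amin:
        return False
    if _angle_deg(frame[d], frame[a], frame[aa]) < amin:
        return False
    return True


def brute_salt_candidate(trajectories, pair, criteria, first_kept) -> bool:
    """Any-O-to-any-N <= cutoff in any retained frame of any replicate."""
    for coords in trajectories:
        for frame in coords[first_kept:]:
            for i in pair.acidic_group:
                for j in pair.basic_group:
                    if _dist(frame[i], frame[j]) <= criteria.sb_candidate_max + EPS:
                        return True
    return False


def brute_com_occupancy(coords, pair, masses, criteria, first_kept) -> float:
    """Frame-count fraction with charged-group COM distance <= cutoff."""
    hits = 0
    frames = coords[first_kept:]
    for frame in frames:
        com = []
        for group in (pair.acidic_group, pair.basic_group):
            m = [masses[i] for i in group]
            tot = sum(m)
            com.append(
                [sum(frame[i][k] * masses[i] for i in group) / tot for k in range(3)]
            )
        if _dist(com[0], com[1]) <= criteria.sb_occupancy_max + EPS:
            hits += 1
    return hits / len(frames)


def brute_min_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Minimum RMSD over proper rotations + translations, found numerically.

    Multi-start quasi-Newton minimisation over rotation vectors after
    centering both clouds; independent of the closed-form SVD solution.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((mob @ r.T - ref) ** 2, axis=1))))

    best = np.inf
    starts = [np.zeros(3)]
    for axis in np.eye(3):
        for angle in (np.pi / 2, np.pi, -np.pi / 2):
            starts.append(axis * angle)
    rng = np.random.default_rng(7)
    starts += list(rng.uniform(-np.pi, np.pi, size=(8, 3)))
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, float(res.fun))
    return best
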