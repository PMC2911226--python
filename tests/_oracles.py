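"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the superposition
oracle uses Horn's quaternion method (a different algorithm from the SVD
route in the package), and the brute-force helpers are plain loops.
"""

import numpy as np


def horn_superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-rigid-fit RMSD of b onto a via Horn's quaternion method."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = bc.T @ ac
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    e2 = (np.sum(ac**2) + np.sum(bc**2) - 2.0 * lam) / len(a)
    return float(np.sqrt(max(e2, 0.0)))


def brute_min_pair_distance(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    best = np.inf
    for p in pts_a:
        for q in pts_b:
            d = float(np.sqrt(np.sum((p - q) ** 2)))
            best = min(best, d)
    return best


def brute_identity_fraction(seq_a: str, seq_b: str, pairs) -> float:
    hits = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
    return hits / len(pairs)


def brute_hbond_count(
    coords_d, donors, antecedents, coords_a, acceptors,
    dist_min, dist_max, angle_min_deg,
) -> int:
    """Plain-loop donor/acceptor pair count inside the geometric window."""
    n = 0
    for di in donors:
        for aj in acceptors:
            r = float(np.linalg.norm(coords_d[di] - coords_a[aj]))
            if not (dist_min <= r <= dist_max):
                continue
            v1 = coords_d[antecedents[di]] - coords_d[di]
            v2 = coords_a[aj] - coords_d[di]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang >= angle_min_deg:
                n += 1
    return n


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
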