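"""Independent numerical oracles, kept separate from the implementation."""

import numpy as np


def quaternion_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    Sxx = A.T @ B
    K = np.empty((4, 4))
    K[0, 0] = Sxx[0, 0] + Sxx[1, 1] + Sxx[2, 2]
    K[0, 1] = K[1, 0] = Sxx[1, 2] - Sxx[2, 1]
    K[0, 2] = K[2, 0] = Sxx[2, 0] - Sxx[0, 2]
    K[0, 3] = K[3, 0] = Sxx[0, 1] - Sxx[1, 0]
    K[1, 1] = Sxx[0, 0] - Sxx[1, 1] - Sxx[2, 2]
    K[1, 2] = K[2, 1] = Sxx[0, 1] + Sxx[1, 0]
    K[1, 3] = K[3, 1] = Sxx[0, 2] + Sxx[2, 0]
    K[2, 2] = -Sxx[0, 0] + Sxx[1, 1] - Sxx[2, 2]
    K[2, 3] = K[3, 2] = Sxx[1, 2] + Sxx[2, 1]
    K[3, 3] = -Sxx[0, 0] - Sxx[1, 1] + Sxx[2, 2]
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(A * A) + np.sum(B * B) - 2.0 * lam) / len(A)
    return float(np.sqrt(max(msd, 0.0)))


def dihedral_atan2(p1, p2, p3, p4) -> float:
    """Praxeolitic single-atan2 torsion formula (independent derivation)."""
    p1, p2, p3, p4 = (np.asarray(p) for p in (p1, p2, p3, p4))
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def plane_normal_eig(points: np.ndarray) -> np.ndarray:
    """Smallest-eigenvector normal of the centered scatter matrix."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    scatter = centered.T @ centered
    w, v = np.linalg.eigh(scatter)
    return v[:, 0]


def sasa_dense(coords, radii, probe=1.4, n_points=10000, seed=12345):
    """High-density random-direction Shrake-Rupley quadrature."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    coords = np.asarray(coords, dtype=float)
    R = np.asarray(radii, dtype=float) + probe
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        sphere = coords[i] + R[i] * pts
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            exposed &= np.linalg.norm(sphere - coords[j], axis=1) >= R[j]
        areas[i] = exposed.mean() * 4.0 * np.pi * R[i] ** 2
    return areas
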