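"""Independent numerical oracles used by the tests.

These deliberately avoid the code paths they check: the quaternion
(Kearsley) eigenvalue method for superposition RMSD, and Monte-Carlo
rejection sampling for volumes of unions of spheres.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def quaternion_rmsd(xa: np.ndarray, xb: np.ndarray) -> float:
    """Best-fit RMSD via the Kearsley 4x4 eigenvalue problem."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    pa = xa - xa.mean(axis=0)
    pb = xb - xb.mean(axis=0)
    m = pa - pb
    p = pa + pb
    xm, ym, zm = m[:, 0], m[:, 1], m[:, 2]
    xp, yp, zp = p[:, 0], p[:, 1], p[:, 2]
    k = np.empty((4, 4))
    k[0, 0] = np.sum(xm * xm + ym * ym + zm * zm)
    k[0, 1] = k[1, 0] = np.sum(yp * zm - ym * zp)
    k[0, 2] = k[2, 0] = np.sum(xm * zp - xp * zm)
    k[0, 3] = k[3, 0] = np.sum(xp * ym - xm * yp)
    k[1, 1] = np.sum(xm * xm + yp * yp + zp * zp)
    k[1, 2] = k[2, 1] = np.sum(xm * ym - xp * yp)
    k[1, 3] = k[3, 1] = np.sum(xm * zm - xp * zp)
    k[2, 2] = np.sum(xp * xp + ym * ym + zp * zp)
    k[2, 3] = k[3, 2] = np.sum(ym * zm - yp * zp)
    k[3, 3] = np.sum(xp * xp + yp * yp + zm * zm)
    lam_min = np.linalg.eigvalsh(k)[0]
    return float(np.sqrt(max(lam_min, 0.0) / len(xa)))


def mc_union_volume(centers: np.ndarray, radius: float, n_points: int,
                    rng: np.random.Generator,
                    bbox_pad: float = 1.0) -> tuple[float, float]:
    """(volume, sigma) of a union of equal spheres by rejection sampling."""
    centers = np.asarray(centers, dtype=float)
    lo = centers.min(axis=0) - radius - bbox_pad
    hi = centers.max(axis=0) + radius + bbox_pad
    box_volume = float(np.prod(hi - lo))
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    dist, _ = cKDTree(centers).query(pts, k=1)
    p = float(np.mean(dist <= radius))
    sigma = box_volume * np.sqrt(max(p * (1 - p), 1e-12) / n_points)
    return box_volume * p, sigma


def mc_ball_volume(radius: float, n_points: int, rng: np.random.Generator,
                   bbox_pad: float = 1.0) -> tuple[float, float]:
    """(volume, sigma) of a single ball, by the same rejection scheme."""
    return mc_union_volume(np.zeros((1, 3)), radius, n_points, rng,
                           bbox_pad=bbox_pad)
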