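"""Independent slow oracle for 3D Zernike moments.

Evaluates the basis Z_nl^m = R_nl(r) Y_l^m(theta, phi) directly at
every point with scipy's spherical harmonics and sums, instead of going
through monomial coefficient tables and geometric moments. Shares
nothing with the package implementation except the published formulas.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.special import sph_harm_y


def oracle_radial(n: int, l: int, r: np.ndarray) -> np.ndarray:
    """R_nl(r) via the textbook coefficient formula, evaluated directly."""
    k = (n - l) // 2
    out = np.zeros_like(r)
    for nu in range(k + 1):
        q = (
            Fraction((-1) ** (k + nu), 4**k)
            * math.comb(2 * k, k)
            * math.comb(k, nu)
            * Fraction(math.comb(2 * (k + l + nu) + 1, 2 * k), math.comb(k + l + nu, k))
        )
        out += float(q) * math.sqrt((2 * l + 4 * k + 3) / 3.0) * r ** (2 * nu + l)
    return out


def oracle_moments(
    points: np.ndarray, weights: np.ndarray, order: int
) -> dict[tuple[int, int, int], complex]:
    """Direct-summation Omega_nl^m for all valid (n, l, m) incl. m < 0.

    ``weights`` is the full per-point measure (f value times normalized
    voxel volume).
    """
    r = np.linalg.norm(points, axis=1)
    safe = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(points[:, 2] / safe, -1.0, 1.0))
    phi = np.arctan2(points[:, 1], points[:, 0])
    out: dict[tuple[int, int, int], complex] = {}
    for n in range(order + 1):
        for l in range(n % 2, n + 1, 2):
            radial = oracle_radial(n, l, r)
            for m in range(-l, l + 1):
                z = radial * sph_harm_y(l, m, theta, phi)
                out[(n, l, m)] = 3.0 / (4.0 * math.pi) * complex(np.sum(weights * np.conj(z)))
    return out


def oracle_invariants(
    moments: dict[tuple[int, int, int], complex], order: int
) -> np.ndarray:
    """F_nl = sqrt(sum_m |Omega_nl^m|^2), ordered (n asc, l asc)."""
    values = []
    for n in range(order + 1):
        for l in range(n % 2, n + 1, 2):
            values.append(
                math.sqrt(sum(abs(moments[(n, l, m)]) ** 2 for m in range(-l, l + 1)))
            )
    return np.array(values)
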