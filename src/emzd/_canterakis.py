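"""Zernike-Canterakis basis in Cartesian monomial form.

The basis functions Z_nl^m = R_nl(r) Y_l^m(theta, phi) are polynomials
in (x, y, z), so each one has an exact finite expansion over monomials
x^r y^s z^t with r + s + t <= n. Expansion coefficients are assembled
from three exact ingredients:

* the radial coefficients q_kl^nu of R_nl(r) = sum_nu q_kl^nu r^(2nu+l),
  k = (n - l)/2, in the normalization that makes the basis orthonormal
  with respect to (3/4pi) * integral over the unit ball;
* the harmonic polynomials e_l^m = r^l Y_l^m, expanded through the
  classical solid-harmonic identity in (x + iy), (x - iy) and z, with
  orthonormal spherical harmonics and the Condon-Shortley phase;
* the multinomial expansion of r^(2nu) = (x^2 + y^2 + z^2)^nu.

Rational parts are carried as exact ``fractions.Fraction`` values and
multiplied by the single irrational prefactor only at the very end, so
the float coefficients are accurate to machine rounding even at n = 20
where raw binomial terms span many orders of magnitude.

Tables are computed once per (order) and cached for the process.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np

__all__ = [
    "valid_nl_pairs",
    "invariant_count",
    "monomial_list",
    "radial_coefficients",
    "conjugate_coefficient_matrix",
]


def valid_nl_pairs(order: int) -> list[tuple[int, int]]:
    """All (n, l) with 0 <= l <= n <= order and n - l even, (n asc, l asc)."""
    if order < 0:
        raise ValueError(f"order must be non-negative, got {order}")
    return [(n, l) for n in range(order + 1) for l in range(n % 2, n + 1, 2)]


def invariant_count(order: int) -> int:
    """Number of rotation invariants F_nl at a given expansion order."""
    return len(valid_nl_pairs(order))


@lru_cache(maxsize=None)
def monomial_list(order: int) -> tuple[tuple[int, int, int], ...]:
    """All monomial exponent triples (r, s, t) with r + s + t <= order."""
    return tuple(
        (r, s, t)
        for r in range(order + 1)
        for s in range(order + 1 - r)
        for t in range(order + 1 - r - s)
    )


def radial_coefficients(n: int, l: int) -> list[float]:
    """Coefficients q_kl^nu of R_nl(r) = sum_nu q_kl^nu r^(2 nu + l)."""
    if (n - l) % 2 or not 0 <= l <= n:
        raise ValueError(f"invalid (n, l) = ({n}, {l})")
    k = (n - l) // 2
    out = []
    for nu in range(k + 1):
        q = (
            Fraction((-1) ** (k + nu), 4**k)
            * math.comb(2 * k, k)
            * math.comb(k, nu)
            * Fraction(math.comb(2 * (k + l + nu) + 1, 2 * k), math.comb(k + l + nu, k))
        )
        out.append(float(q) * math.sqrt((2 * l + 4 * k + 3) / 3.0))
    return out


def _solid_harmonic_monomials(l: int, m: int) -> dict[tuple[int, int, int], complex]:
    """e_l^m = r^l Y_l^m as {(r, s, t): coefficient} over x^r y^s z^t."""
    terms: dict[tuple[int, int, int], list[Fraction]] = {}
    for p in range(l + 1):
        q = p - m
        s = l - p - q
        if q < 0 or s < 0:
            continue
        base = Fraction((-1) ** p, 2 ** (p + q)) / (
            math.factorial(p) * math.factorial(q) * math.factorial(s)
        )
        for a in range(p + 1):
            for b in range(q + 1):
                coeff = base * math.comb(p, a) * math.comb(q, b)
                ipow = (a - b) % 4  # i^a * (-i)^b = i^(a-b)
                key = (p - a + q - b, a + b, s)
                acc = terms.setdefault(key, [Fraction(0), Fraction(0)])
                if ipow == 0:
                    acc[0] += coeff
                elif ipow == 1:
                    acc[1] += coeff
                elif ipow == 2:
                    acc[0] -= coeff
                else:
                    acc[1] -= coeff
    prefactor = math.sqrt(
        (2 * l + 1) * math.factorial(l + m) * math.factorial(l - m) / (4.0 * math.pi)
    )
    return {
        key: complex(float(re), float(im)) * prefactor
        for key, (re, im) in terms.items()
        if re != 0 or im != 0
    }


def _zernike_monomials(n: int, l: int, m: int) -> dict[tuple[int, int, int], complex]:
    """Z_nl^m as {(r, s, t): coefficient}."""
    harmonic = _solid_harmonic_monomials(l, m)
    out: dict[tuple[int, int, int], complex] = {}
    for nu, q in enumerate(radial_coefficients(n, l)):
        for i in range(nu + 1):
            for j in range(nu + 1 - i):
                k2 = nu - i - j
                mult = q * (
                    math.factorial(nu)
                    / (math.factorial(i) * math.factorial(j) * math.factorial(k2))
                )
                for (r, s, t), c in harmonic.items():
                    key = (r + 2 * i, s + 2 * j, t + 2 * k2)
                    out[key] = out.get(key, 0j) + mult * c
    return out


@lru_cache(maxsize=4)
def conjugate_coefficient_matrix(
    order: int,
) -> tuple[list[tuple[int, int, int]], np.ndarray]:
    """Dense matrix C with conj(Z_nl^m) monomial coefficients, m >= 0 only.

    Returns ``(triples, C)`` where ``triples`` lists (n, l, m >= 0) in
    (n asc, l asc, m asc) order and ``C[i] @ M`` gives the moment
    integrand sum for geometric moment vector ``M`` over
    :func:`monomial_list` (before the 3/(4 pi) scaling). Negative-m
    moments follow from conjugate symmetry for real-valued input.
    """
    monomials = monomial_list(order)
    index = {mono: i for i, mono in enumerate(monomials)}
    triples = [(n, l, m) for n, l in valid_nl_pairs(order) for m in range(l + 1)]
    C = np.zeros((len(triples), len(monomials)), dtype=np.complex128)
    for row, (n, l, m) in enumerate(triples):
        for mono, coeff in _zernike_monomials(n, l, m).items():
            C[row, index[mono]] = np.conj(coeff)
    return triples, C
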