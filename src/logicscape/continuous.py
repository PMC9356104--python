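"""Continuous interpolation of discrete landscapes, entropy, free energy.

The discrete energy T on {0,1}^n has a unique multilinear (pseudo-
Boolean) extension

    E(s) = omega_0 + sum_i s_i omega_i + sum_{i<j} s_i s_j omega_ij + ...

first-order in every coordinate and agreeing with T at all binary
corners.  Indexing coefficients by subset bitmask b, the corner values
satisfy ``M omega = T`` where ``M_ab = 1`` iff ``b`` is a bitwise subset
of ``a``.  M is the n-fold Kronecker power of ``[[1,0],[1,1]]`` and its
inverse the power of ``[[1,0],[-1,1]]``, so ``omega = M^-1 T`` is
integer-exact for integer T.  In practice omega is computed by the fast
subset Moebius transform in O(n 2^n) without materialising M.

Pairing E with the ideal-mixing entropy
``S(s) = -sum_i [s_i log s_i + (1-s_i) log(1-s_i)]`` (natural log,
0 log 0 := 0) gives the free energy F = E - T_temp * S, whose
stationary points satisfy the sigmoid relation
``s_i = logistic(-dE/ds_i / T_temp)``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .landscape import EnergyLandscape

__all__ = [
    "build_M",
    "omega_from_T",
    "energy_continuous",
    "entropy",
    "free_energy",
    "write_omega",
]


def build_M(n: int) -> tuple[np.ndarray, np.ndarray]:
    """The 2^n x 2^n subset-indicator matrix and its inverse.

    ``M[a, b] = 1`` iff ``b & a == b``.  Built by the recursive block
    rule, equivalently Kronecker powers of the 2x2 base; integer exact.
    Guarded at ``n > 14`` (the dense matrix is the bottleneck; use
    :func:`omega_from_T` for larger systems).
    """
    if not 1 <= n <= 14:
        raise ValueError("n must be in 1..14 (use omega_from_T for large systems)")
    base = np.array([[1, 0], [1, 1]], dtype=np.int64)
    base_inv = np.array([[1, 0], [-1, 1]], dtype=np.int64)
    M, Minv = base, base_inv
    for _ in range(n - 1):
        M = np.kron(base, M)
        Minv = np.kron(base_inv, Minv)
    return M, Minv


def _as_T(T: EnergyLandscape | Sequence[float]) -> np.ndarray:
    arr = T.energies if isinstance(T, EnergyLandscape) else np.asarray(T, dtype=float)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 1 or arr.size == 0 or arr.size & (arr.size - 1):
        raise ValueError("T must be a vector of length 2^n")
    return arr


def omega_from_T(T: EnergyLandscape | Sequence[float]) -> np.ndarray:
    """Multilinear coefficients ``omega = M^-1 T`` via the Moebius transform.

    ``omega[b] = sum_{c subset of b} (-1)^{|b \\ c|} T[c]``; exact
    integers for integer T.
    """
    omega = _as_T(T).copy()
    n = omega.size.bit_length() - 1
    for i in range(n):
        bit = 1 << i
        hi = (np.arange(omega.size) & bit).astype(bool)
        omega[hi] -= omega[~hi]
    if np.allclose(omega, np.round(omega)):
        omega = np.round(omega)
    return omega


def energy_continuous(omega: Sequence[float], s: Sequence[float]) -> float:
    """Evaluate the multilinear form at ``s`` in [0,1]^n.

    At binary corners this reproduces the discrete energy exactly.
    Evaluated by successive partial substitution, O(n 2^n).
    """
    omega = np.asarray(omega, dtype=float)
    s = np.asarray(s, dtype=float)
    n = omega.size.bit_length() - 1
    if omega.size != 1 << n or s.size != n:
        raise ValueError(f"omega length {omega.size} incompatible with s length {s.size}")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("coordinates must lie in [0, 1]")
    # substitute one coordinate at a time; adjacent entries pair masks
    # (b, b | lowest-remaining-bit), so the array halves each round
    vals = omega
    for i in range(n):
        vals = vals.reshape(-1, 2)
        vals = vals[:, 0] + s[i] * vals[:, 1]
    return float(vals[0])


def entropy(s: Sequence[float]) -> float:
    """Ideal-mixing entropy, natural log, with 0 log 0 := 0 at corners."""
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("coordinates must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(s > 0, s * np.log(s), 0.0) + np.where(
            s < 1, (1 - s) * np.log(1 - s), 0.0
        )
    return float(-np.sum(terms))


def free_energy(
    omega: Sequence[float], s: Sequence[float], temperature: float
) -> float:
    """F(s) = E(s) - temperature * S(s)."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return energy_continuous(omega, s) - temperature * entropy(s)


def write_omega(omega: Sequence[float], path) -> None:
    """TSV export: ``subset_mask<TAB>coefficient``."""
    from pathlib import Path

    omega = np.asarray(omega, dtype=float)
    lines = ["subset_mask\tcoefficient"]
    for b, w in enumerate(omega):
        lines.append(f"{b}\t{w:g}")
    Path(path).write_text("\n".join(lines) + "\n")
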