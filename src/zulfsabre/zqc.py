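"""Coherence-order labeling, the ZQC subspace, projections and dimension formulas.

In the product basis (descending m per site) every Hilbert state has a total
spin projection Fz equal to the sum of its per-site m values.  A Liouville
ket-bra element |r><c| carries the coherence order q = Fz(r) - Fz(c); the
zero-quantum coherence (ZQC) subspace is the span of all elements with q = 0.
Because the low-field Hamiltonian, the RFF relaxation superoperator and the
chemical-exchange maps all conserve q, a density matrix that starts diagonal
(q = 0) never leaves this subspace, and every superoperator may be projected
onto it exactly by index gathering.

Half-integer Fz values are handled internally as doubled integers so block
keys are exact.

Dimension formulas: a system of n non-equivalent spin-1/2 nuclei plus
effective spins K1, K2, ... has per-Fz Hilbert dimensions given by the
convolution of per-site m-degeneracies, and

    dim(ZQC) = sum_Fz dim(H_Fz)^2,

which for n spins-1/2 and no groups equals C(2n, n) and behaves as
4^n / sqrt(pi n) for large n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.sparse as sp

from .spin_system import (
    SpinSystem,
    SpinSystemError,
    _check_half_integer,
    enumerate_configs,
    reduce_system,
)

__all__ = [
    "hilbert_fz2_labels",
    "LabeledBasis",
    "ZqcIndex",
    "coherence_orders",
    "fz_block_sizes",
    "zqc_dimension",
    "matrix_dimensions",
    "project_superoperator",
]


def hilbert_fz2_labels(spins: list[float]) -> np.ndarray:
    """Doubled total-Fz label (integer) of every product basis state."""
    labels = np.zeros(1, dtype=np.int64)
    for s in spins:
        s2 = _check_half_integer(s)
        m2 = s2 - 2 * np.arange(s2 + 1)
        labels = (labels[:, None] + m2[None, :]).ravel()
    return labels


@dataclass(frozen=True)
class LabeledBasis:
    """Hilbert basis of a reduced system with per-state doubled-Fz labels."""

    spins: tuple[float, ...]
    fz2: np.ndarray

    @classmethod
    def of(cls, system_or_spins) -> "LabeledBasis":
        spins = (
            tuple(system_or_spins.spins)
            if isinstance(system_or_spins, SpinSystem)
            else tuple(system_or_spins)
        )
        return cls(spins=spins, fz2=hilbert_fz2_labels(list(spins)))

    @property
    def dim(self) -> int:
        return len(self.fz2)


def coherence_orders(system_or_spins) -> np.ndarray:
    """Doubled coherence order 2q of every Liouville element, row-major.

    Element |r><c| sits at linear index r*d + c and has q = Fz(r) - Fz(c).
    """
    basis = LabeledBasis.of(system_or_spins)
    return (basis.fz2[:, None] - basis.fz2[None, :]).ravel()


@dataclass(frozen=True)
class ZqcIndex:
    """Ordered ZQC ket-bra list with gather indices into the full Liouville space.

    Deterministic order: ascending Fz block, then ket index, then bra index.
    """

    hilbert_dim: int
    ket: np.ndarray
    bra: np.ndarray
    linear: np.ndarray

    @classmethod
    def of(cls, system_or_spins) -> "ZqcIndex":
        basis = LabeledBasis.of(system_or_spins)
        d = basis.dim
        kets, bras = [], []
        for v in np.unique(basis.fz2):  # ascending Fz
            idx = np.flatnonzero(basis.fz2 == v)
            r, c = np.meshgrid(idx, idx, indexing="ij")
            kets.append(r.ravel())
            bras.append(c.ravel())
        ket = np.concatenate(kets)
        bra = np.concatenate(bras)
        return cls(hilbert_dim=d, ket=ket, bra=bra, linear=ket * d + bra)

    @property
    def dim(self) -> int:
        return len(self.linear)

    def gather(self, full_vector: np.ndarray) -> np.ndarray:
        return np.asarray(full_vector).ravel()[self.linear]

    def scatter(self, zqc_vector: np.ndarray) -> np.ndarray:
        full = np.zeros(self.hilbert_dim**2, dtype=np.asarray(zqc_vector).dtype)
        full[self.linear] = zqc_vector
        return full


# ----------------------------------------------------------------------
# dimension formulas
# ----------------------------------------------------------------------

def fz_block_sizes(n_noneq: int, k_values: list = ()) -> np.ndarray:
    """Hilbert-space dimension of each Fz block (ascending Fz), by convolution.

    n_noneq spin-1/2 sites contribute a binomial profile; each effective spin
    K contributes a flat profile of width 2K+1.
    """
    if n_noneq < 0:
        raise SpinSystemError("n_noneq must be non-negative")
    poly = np.ones(1, dtype=object)
    if n_noneq:
        binom = np.array([math.comb(n_noneq, i) for i in range(n_noneq + 1)], dtype=object)
        poly = np.convolve(poly, binom)
    for k in k_values:
        k2 = _check_half_integer(k, "K")
        poly = np.convolve(poly, np.ones(k2 + 1, dtype=object))
    return poly


def zqc_dimension(n_noneq: int, k_values: list = ()) -> int:
    """Exact ZQC dimension: sum over Fz of squared Hilbert-block dimensions."""
    return int(sum(int(c) ** 2 for c in fz_block_sizes(n_noneq, k_values)))


def _system_zqc_dimension(system: SpinSystem) -> int:
    """ZQC dimension of a reduced system from its site spins."""
    n_noneq = sum(1 for s in system.spins if s == 0.5)
    ks = [s for s in system.spins if s != 0.5]
    return zqc_dimension(n_noneq, ks)


def matrix_dimensions(substrate: SpinSystem, complex_: SpinSystem) -> dict:
    """Per-configuration and maximum matrix dimensions of the three SABRE
    representations (full / K-reduced / ZQC-reduced).

    The full dimension is 4^N + 4^(N+2) for N substrate spins; the K-reduced
    dimension of a configuration is the sum of squared reduced Hilbert
    dimensions; the ZQC dimension is the sum of the two ZQC subspace sizes.
    Group names must agree between substrate and complex.
    """
    n_sub = len(substrate.nuclei)
    n_cx = len(complex_.nuclei)
    if n_cx != n_sub + 2:
        raise SpinSystemError(
            f"complex must contain the substrate plus two hydrides "
            f"({n_cx} vs {n_sub} + 2 spins)"
        )
    full = 4**n_sub + 4**n_cx
    per_config = []
    for cfg in enumerate_configs(substrate):
        red_cx = reduce_system(complex_, cfg.k_values) if complex_.groups else complex_
        ds = cfg.reduced_system.hilbert_dim
        dc = red_cx.hilbert_dim
        per_config.append(
            {
                "config": cfg.label(),
                "weight": cfg.weight,
                "k_reduced": ds**2 + dc**2,
                "zqc": _system_zqc_dimension(cfg.reduced_system)
                + _system_zqc_dimension(red_cx),
                "zqc_substrate": _system_zqc_dimension(cfg.reduced_system),
                "zqc_complex": _system_zqc_dimension(red_cx),
            }
        )
    return {
        "full": full,
        "per_config": per_config,
        "k_reduced_max": max(c["k_reduced"] for c in per_config),
        "zqc_max": max(c["zqc"] for c in per_config),
    }


def project_superoperator(
    s_op: sp.spmatrix, rows: ZqcIndex, cols: ZqcIndex
) -> sp.csr_matrix:
    """Gather the q=0 rows and columns of a superoperator.

    Exact (information-free) for any superoperator that conserves coherence
    order; the ket-bra basis is orthonormal so projection is pure indexing.
    """
    s_op = sp.csr_matrix(s_op)
    if s_op.shape != (rows.hilbert_dim**2, cols.hilbert_dim**2):
        raise SpinSystemError(
            f"superoperator shape {s_op.shape} does not match index spaces "
            f"({rows.hilbert_dim**2}, {cols.hilbert_dim**2})"
        )
    return s_op[rows.linear, :][:, cols.linear].tocsr()
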