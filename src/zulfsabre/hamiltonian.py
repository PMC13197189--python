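"""Low-field Hamiltonian of a (reduced) spin system and its superoperator.

H = -B0 sum_l gamma_l (1 + 1e-6 * delta_l) Iz_l + 2*pi sum_{l<m} J_lm (I_l . I_m)

in angular-frequency units (rad/s): the Zeeman term carries gamma*B0 directly
while J couplings, given in Hz, are scaled by 2*pi.  Chemical shifts delta_l
(ppm) default to zero, appropriate at zero/ultralow field, but are accepted.
Effective spins K enter exactly like physical nuclei, carrying the group's
gamma and common external couplings; intra-group couplings never appear in a
reduced system and do not affect the dynamics of a K block.

Liouville-space mapping uses row-major vectorization, vec(|r><c|) -> r*d + c,
under which the commutation superoperator of A is A x 1 - 1 x A^T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .operators import embed, scalar_coupling, spin_matrices
from .spin_system import SpinSystem, SpinSystemError

__all__ = ["FieldProtocol", "build_hamiltonian", "commutation_superoperator"]


@dataclass(frozen=True)
class FieldProtocol:
    """Piecewise-constant magnetic-field protocol: segments of (B0 [T], duration [s])."""

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(tuple(s) for s in self.segments))
        for b0, dur in self.segments:
            if not np.isfinite(b0):
                raise SpinSystemError(f"field {b0} is not finite")
            if not dur > 0:
                raise SpinSystemError(f"segment duration must be positive, got {dur}")

    @classmethod
    def constant(cls, b0: float, duration: float) -> "FieldProtocol":
        return cls(((b0, duration),))

    @classmethod
    def ramp(cls, b_start: float, b_end: float, duration: float, n_steps: int) -> "FieldProtocol":
        """Linear ramp discretized into n piecewise-constant steps (midpoint fields)."""
        if n_steps < 1:
            raise SpinSystemError("ramp needs at least one step")
        edges = np.linspace(b_start, b_end, n_steps + 1)
        mids = (edges[:-1] + edges[1:]) / 2.0
        return cls(tuple((float(b), duration / n_steps) for b in mids))

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments)


def build_hamiltonian(system: SpinSystem, b0: float) -> sp.csr_matrix:
    """Hilbert-space Hamiltonian (rad/s) of a reduced system at field b0 (tesla).

    Hermitian and commuting with total Fz by construction.  Systems passed
    here must already be reduced (no equivalence groups).
    """
    if system.groups:
        raise SpinSystemError("build_hamiltonian expects a reduced (group-free) system")
    dims = system.dims
    spins = system.spins
    d = system.hilbert_dim
    h = sp.csr_matrix((d, d), dtype=complex)
    for i, nuc in enumerate(system.nuclei):
        w = -b0 * nuc.gamma * (1.0 + 1e-6 * nuc.shift_ppm)
        if w != 0.0:
            h = h + w * embed(spin_matrices(nuc.spin)["Iz"], i, dims)
    labels = system.labels
    for i in range(len(labels)):
        for k in range(i + 1, len(labels)):
            j = system.j(labels[i], labels[k])
            if j != 0.0:
                h = h + (2.0 * np.pi * j) * scalar_coupling(i, k, spins)
    return h.tocsr()


def commutation_superoperator(a: sp.spmatrix | np.ndarray) -> sp.csr_matrix:
    """Commutation superoperator of A: acting on vec(X) it returns vec([A, X]).

    Row-major vectorization: the superoperator is A x 1 - 1 x A^T, so its
    spectrum is the set of pairwise eigenvalue differences of A.
    """
    a = sp.csr_matrix(a)
    if a.shape[0] != a.shape[1]:
        raise SpinSystemError(f"commutation superoperator needs a square matrix, got {a.shape}")
    d = a.shape[0]
    eye = sp.identity(d, format="csr", dtype=complex)
    out = sp.kron(a, eye, format="csr") - sp.kron(eye, a.T, format="csr")
    out.eliminate_zeros()
    return out
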