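"""Chemical-exchange maps between substrate and complex Liouville spaces.

Substrate dissociation traces the complex density matrix over the two
hydride spins; association attaches a fresh parahydrogen singlet to the
free-substrate density matrix:

    TrH2 :  rho_C  ->  Tr_{H2} rho_C          (complex -> substrate)
    Kron :  rho_S  ->  rho_S (x) rho_pH2      (substrate -> complex)

Site-ordering contract: the complex Hilbert space is (substrate sites, in
substrate order) (x) hydride-1 (x) hydride-2, so both maps are pure index
arithmetic.  Both maps conserve the coherence order (the singlet is a q = 0
state and the partial trace only connects equal hydride indices), so their
restriction to the ZQC subspaces is exact.  Rates do not appear here; they
multiply these maps in the master-equation generator.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .spin_system import SpinSystemError
from .zqc import ZqcIndex

__all__ = [
    "singlet_state",
    "partial_trace_map",
    "kron_map",
    "project_exchange",
]


def singlet_state() -> np.ndarray:
    """Density matrix of parahydrogen: the two-proton singlet projector |S><S|,
    |S> = (|+-> - |-+>)/sqrt(2) in the descending-m product basis (++, +-, -+, --).
    """
    ket = np.array([0.0, 1.0, -1.0, 0.0]) / np.sqrt(2.0)
    return np.outer(ket, ket).astype(complex)


def partial_trace_map(substrate_dim: int) -> sp.csr_matrix:
    """Sparse map (complex Liouville -> substrate Liouville) tracing out the
    last two spin-1/2 sites: (rho_S)_{rc} = sum_h (rho_C)_{(r,h),(c,h)}.
    """
    if substrate_dim < 1:
        raise SpinSystemError("substrate dimension must be positive")
    ds = substrate_dim
    dc = 4 * ds
    r, c, h = np.meshgrid(np.arange(ds), np.arange(ds), np.arange(4), indexing="ij")
    rows = (r * ds + c).ravel()
    cols = ((r * 4 + h) * dc + (c * 4 + h)).ravel()
    data = np.ones(rows.size)
    return sp.csr_matrix((data, (rows, cols)), shape=(ds**2, dc**2), dtype=complex)


def kron_map(substrate_dim: int, rho_ph2: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse map (substrate Liouville -> complex Liouville) attaching a
    hydride-pair state: (rho_C)_{(r,h),(c,h')} = (rho_S)_{rc} * (rho_pH2)_{h,h'}.

    rho_ph2 defaults to the parahydrogen singlet and must have unit trace.
    """
    if substrate_dim < 1:
        raise SpinSystemError("substrate dimension must be positive")
    if rho_ph2 is None:
        rho_ph2 = singlet_state()
    rho_ph2 = np.asarray(rho_ph2, dtype=complex)
    if rho_ph2.shape != (4, 4):
        raise SpinSystemError("hydride-pair state must be a 4x4 density matrix")
    if abs(np.trace(rho_ph2) - 1.0) > 1e-12:
        raise SpinSystemError(
            f"hydride-pair state must have unit trace, got {np.trace(rho_ph2):.6g}"
        )
    ds = substrate_dim
    dc = 4 * ds
    r, c, h, hp = np.meshgrid(
        np.arange(ds), np.arange(ds), np.arange(4), np.arange(4), indexing="ij"
    )
    rows = ((r * 4 + h) * dc + (c * 4 + hp)).ravel()
    cols = (r * ds + c).ravel()
    data = rho_ph2[h.ravel(), hp.ravel()]
    keep = data != 0
    return sp.csr_matrix(
        (data[keep], (rows[keep], cols[keep])), shape=(dc**2, ds**2), dtype=complex
    )


def project_exchange(
    trace_map: sp.spmatrix,
    kron_map_: sp.spmatrix,
    zqc_s: ZqcIndex,
    zqc_c: ZqcIndex,
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """ZQC blocks of the exchange pair: (TrH2 restricted to ZQC_C -> ZQC_S,
    Kron restricted to ZQC_S -> ZQC_C).  Exact because both maps conserve q.
    """
    tr = sp.csr_matrix(trace_map)
    kr = sp.csr_matrix(kron_map_)
    ds2, dc2 = zqc_s.hilbert_dim**2, zqc_c.hilbert_dim**2
    if tr.shape != (ds2, dc2) or kr.shape != (dc2, ds2):
        raise SpinSystemError("exchange map shapes do not match the ZQC index spaces")
    tr_z = tr[zqc_s.linear, :][:, zqc_c.linear].tocsr()
    kr_z = kr[zqc_c.linear, :][:, zqc_s.linear].tocsr()
    return tr_z, kr_z
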