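"""Angular-momentum operators for arbitrary spin and tensor-product embedding.

Single-site matrices are dense and use the descending-m basis convention
(m = +s first), so that Iz = diag(s, s-1, ..., -s) and the total-Fz label of
a product state is simply the sum of per-site m values read off the index.
Composite operators are scipy CSR matrices; downstream modules stay sparse
throughout, which is what makes >10-spin Liouville spaces tractable.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .spin_system import SpinSystem, SpinSystemError, _check_half_integer

__all__ = [
    "spin_matrices",
    "spherical_tensor",
    "embed",
    "scalar_coupling",
    "total_fz",
    "site_m_values",
]


def site_m_values(s: float) -> np.ndarray:
    """Per-basis-state m values of one spin-s site, descending: s, s-1, ..., -s."""
    s2 = _check_half_integer(s)
    return (s2 - 2 * np.arange(s2 + 1)) / 2.0


def spin_matrices(s: float) -> dict[str, np.ndarray]:
    """Standard spin matrices Ix, Iy, Iz, I+, I-, identity for spin s.

    Dense (2s+1)-dimensional matrices in the descending-m basis;
    I+- = Ix +- i Iy with the usual sqrt(s(s+1) - m(m+1)) matrix elements.
    """
    if s < 0:
        raise SpinSystemError(f"spin must be non-negative, got {s}")
    m = site_m_values(s)
    d = len(m)
    iz = np.diag(m).astype(complex)
    iplus = np.zeros((d, d), dtype=complex)
    # basis index i has m_i = s - i; I+ raises m, i.e. maps index i -> i-1
    for i in range(1, d):
        iplus[i - 1, i] = np.sqrt(s * (s + 1) - m[i] * (m[i] + 1))
    iminus = iplus.conj().T
    ix = (iplus + iminus) / 2.0
    iy = (iplus - iminus) / 2.0j
    return {
        "Ix": ix,
        "Iy": iy,
        "Iz": iz,
        "Iplus": iplus,
        "Iminus": iminus,
        "identity": np.eye(d, dtype=complex),
    }


def spherical_tensor(s: float, m: int) -> np.ndarray:
    """Rank-1 irreducible spherical tensor component T_{1,m} for spin s.

    T_{1,+1} = -(Ix + iIy)/sqrt(2),  T_{1,0} = Iz,  T_{1,-1} = (Ix - iIy)/sqrt(2).
    Valid for spin-1/2 nuclei and effective spins K alike.
    """
    ops = spin_matrices(s)
    if m == 0:
        return ops["Iz"]
    if m == 1:
        return -ops["Iplus"] / np.sqrt(2.0)
    if m == -1:
        return ops["Iminus"] / np.sqrt(2.0)
    raise SpinSystemError(f"rank-1 tensor component m must be in {{-1,0,1}}, got {m}")


def embed(op: np.ndarray, site: int, dims: list[int]) -> sp.csr_matrix:
    """Embed a single-site operator into the product space: 1 x ... x op x ... x 1."""
    op = np.asarray(op)
    if not (0 <= site < len(dims)):
        raise SpinSystemError(f"site index {site} out of range for {len(dims)} sites")
    if op.shape != (dims[site], dims[site]):
        raise SpinSystemError(
            f"operator shape {op.shape} does not match site dimension {dims[site]}"
        )
    left = int(np.prod(dims[:site], dtype=np.int64))
    right = int(np.prod(dims[site + 1:], dtype=np.int64))
    out = sp.kron(
        sp.kron(sp.identity(left, format="csr"), sp.csr_matrix(op), format="csr"),
        sp.identity(right, format="csr"),
        format="csr",
    )
    out.eliminate_zeros()
    return out


def scalar_coupling(site_a: int, site_b: int, spins: list[float]) -> sp.csr_matrix:
    """Scalar product (I_a . I_b) on the composite space.

    Built as Iz Iz + (I+ I- + I- I+)/2 from embedded ladder operators.
    """
    if site_a == site_b:
        raise SpinSystemError("scalar coupling requires two distinct sites")
    dims = [_check_half_integer(s) + 1 for s in spins]
    oa = spin_matrices(spins[site_a])
    ob = spin_matrices(spins[site_b])
    za, zb = embed(oa["Iz"], site_a, dims), embed(ob["Iz"], site_b, dims)
    pa, pb = embed(oa["Iplus"], site_a, dims), embed(ob["Iplus"], site_b, dims)
    ma, mb = embed(oa["Iminus"], site_a, dims), embed(ob["Iminus"], site_b, dims)
    return (za @ zb + (pa @ mb + ma @ pb) / 2.0).tocsr()


def total_fz(spins: list[float]) -> sp.csr_matrix:
    """Total z projection Fz = sum_l Iz_l (diagonal in the product basis)."""
    dims = [_check_half_integer(s) + 1 for s in spins]
    out = sp.csr_matrix((int(np.prod(dims)),) * 2, dtype=complex)
    for i, s in enumerate(spins):
        out = out + embed(spin_matrices(s)["Iz"], i, dims)
    return out.tocsr()


def system_operator(system: SpinSystem, label: str, component: str = "Iz") -> sp.csr_matrix:
    """Embedded single-site operator of the named nucleus of a (reduced) system."""
    try:
        site = system.labels.index(label)
    except ValueError as exc:
        raise KeyError(label) from exc
    return embed(spin_matrices(system.spins[site])[component], site, system.dims)
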