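"""Redfield relaxation from isotropic randomly fluctuating fields (RFF).

In the extreme-narrowing (fast-motion) limit the RFF mechanism gives

    Gamma = -(1/2) sum_{n,l} C_nl / sqrt(T1n T1l)
            sum_{m=-1..1} (-1)^m TT_{1,-m}^n TT_{1,m}^l,

where TT_{1,m}^n is the commutation superoperator of the rank-1 spherical
tensor T_{1,m} embedded on site n, T1n the longitudinal relaxation time, and
C_nl in [0, 1] the correlation between the local fields at sites n and l.
The default model keeps only the diagonal terms (independent fields, one
term per site with rate 1/T1n); a group of magnetically equivalent nuclei is
represented either by its single effective spin K (one collective term with
the group T1 -- the reduced form used by the engine) or, in the unreduced
representation, by fully correlated fields C_nl = 1 within the group.

This mechanism yields T2 = T1 per spin, preserves the trace, commutes with
the total-Fz superoperator (hence conserves coherence order) and, for
correlated groups, with the group total-spin superoperator K^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .hamiltonian import commutation_superoperator
from .operators import embed, spherical_tensor
from .spin_system import SpinSystem, SpinSystemError

__all__ = ["RelaxationSpec", "correlated_group_spec", "build_relaxation_superoperator"]


@dataclass(frozen=True)
class RelaxationSpec:
    """Explicit per-site T1 list (None entries relax nothing) and optional
    symmetric correlation matrix with unit diagonal and entries in [0, 1].

    When correlation is None only the independent (diagonal) terms are built.
    """

    t1: tuple[float | None, ...]
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "t1", tuple(self.t1))
        for t in self.t1:
            if t is not None and not t > 0:
                raise SpinSystemError(f"T1 must be positive or None, got {t}")
        c = self.correlation
        if c is not None:
            c = np.asarray(c, dtype=float)
            n = len(self.t1)
            if c.shape != (n, n):
                raise SpinSystemError(f"correlation matrix shape {c.shape} != ({n}, {n})")
            if not np.allclose(c, c.T):
                raise SpinSystemError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(c), 1.0):
                raise SpinSystemError("correlation matrix must have unit diagonal")
            if (c < -1e-12).any() or (c > 1 + 1e-12).any():
                raise SpinSystemError("correlation entries must lie in [0, 1]")
            object.__setattr__(self, "correlation", c)


def correlated_group_spec(system: SpinSystem) -> RelaxationSpec:
    """Spec for the *unreduced* representation of a system with groups:
    C_nl = 1 within each equivalence group (shared group T1), 0 otherwise.
    """
    labels = system.labels
    t1: list[float | None] = [n.t1 for n in system.nuclei]
    c = np.eye(len(labels))
    for g in system.groups:
        idx = [labels.index(m) for m in g.members]
        for i in idx:
            if g.t1 is not None:
                t1[i] = g.t1
            for k in idx:
                c[i, k] = 1.0
    return RelaxationSpec(t1=tuple(t1), correlation=c)


def _site_tensor_superops(system: SpinSystem, site: int) -> dict[int, sp.csr_matrix]:
    dims = system.dims
    s = system.spins[site]
    return {
        m: commutation_superoperator(embed(spherical_tensor(s, m), site, dims))
        for m in (-1, 0, 1)
    }


def build_relaxation_superoperator(
    system: SpinSystem, spec: RelaxationSpec | None = None
) -> sp.csr_matrix:
    """RFF Redfield superoperator on the full Liouville space of a reduced system.

    With spec=None, each site n with a T1 contributes the independent term
    -(1/(2 T1n)) sum_m (-1)^m TT_{1,-m}^n TT_{1,m}^n; an effective spin-K site
    carries its group's collective relaxation automatically.  Sites with
    t1=None are omitted.  A spec with a correlation matrix adds the cross
    terms -(1/2) C_nl / sqrt(T1n T1l) sum_m (-1)^m TT_{1,-m}^n TT_{1,m}^l.
    """
    if system.groups and spec is None:
        raise SpinSystemError(
            "build_relaxation_superoperator on an unreduced system needs an "
            "explicit RelaxationSpec (see correlated_group_spec)"
        )
    n_sites = len(system.nuclei)
    if spec is None:
        spec = RelaxationSpec(t1=tuple(n.t1 for n in system.nuclei))
    if len(spec.t1) != n_sites:
        raise SpinSystemError("RelaxationSpec length does not match number of sites")

    dim_l = system.hilbert_dim**2
    gamma = sp.csr_matrix((dim_l, dim_l), dtype=complex)
    cache: dict[int, dict[int, sp.csr_matrix]] = {}

    def tensors(site: int) -> dict[int, sp.csr_matrix]:
        if site not in cache:
            cache[site] = _site_tensor_superops(system, site)
        return cache[site]

    c = spec.correlation
    for n in range(n_sites):
        for l in range(n_sites):
            if n == l:
                cnl = 1.0
            elif c is None:
                continue
            else:
                cnl = float(c[n, l])
                if cnl == 0.0:
                    continue
            t1n, t1l = spec.t1[n], spec.t1[l]
            if t1n is None or t1l is None:
                continue
            rate = cnl / np.sqrt(t1n * t1l)
            tn, tl = tensors(n), tensors(l)
            for m in (-1, 0, 1):
                gamma = gamma - 0.5 * rate * (-1.0) ** m * (tn[-m] @ tl[m])
    gamma.eliminate_zeros()
    return gamma.tocsr()
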