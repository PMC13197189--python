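"""Unreduced reference solvers used for validation of the ZQC path.

All three representations (full / k_reduced / zqc) share the operator,
relaxation and exchange builders; only the state representation differs, so
agreement between them isolates the reduction logic.  The full solver keeps
every physical spin-1/2 explicit (with correlated fluctuating fields inside
equivalence groups); the K-reduced solver uses effective spins but no ZQC
projection.  Both refuse dimensions above a configurable cap.
"""

from __future__ import annotations

import math

from .sabre_engine import SabreModel, solve
from .spin_system import SpinSystemError
from .zqc import matrix_dimensions, zqc_dimension

__all__ = [
    "DEFAULT_DIMENSION_CAP",
    "solve_full",
    "solve_k_reduced",
    "solve_zqc",
    "dimension_table",
]

DEFAULT_DIMENSION_CAP = 1_000_000


def solve_full(
    model: SabreModel, b0: float, tpol: float, cap: int = DEFAULT_DIMENSION_CAP
) -> dict[str, float]:
    """Full-Liouville SABRE solve (no effective spins, no ZQC projection)."""
    n = len(model.substrate.nuclei)
    dim = 4**n + 4 ** (n + 2)
    if dim > cap:
        raise SpinSystemError(
            f"full SABRE dimension 4^{n} + 4^{n + 2} = {dim} exceeds cap {cap}"
        )
    return solve(model, b0, tpol, representation="full")


def solve_k_reduced(
    model: SabreModel, b0: float, tpol: float, cap: int = DEFAULT_DIMENSION_CAP
) -> dict[str, float]:
    """Effective-spin-reduced solve on the full Liouville space of each config."""
    dims = matrix_dimensions(model.substrate, model.complex)
    if dims["k_reduced_max"] > cap:
        raise SpinSystemError(
            f"K-SABRE dimension {dims['k_reduced_max']} exceeds cap {cap}"
        )
    return solve(model, b0, tpol, representation="k_reduced")


def solve_zqc(model: SabreModel, b0: float, tpol: float) -> dict[str, float]:
    return solve(model, b0, tpol, representation="zqc")


def dimension_table(nmax: int) -> list[dict]:
    """Dimension-vs-N benchmark rows for group-free substrates N = 1..nmax.

    full = 4^N + 4^(N+2); zqc = C(2N, N) + C(2N+4, N+2); the full/zqc ratio
    approaches sqrt(pi N) for large N.
    """
    rows = []
    for n in range(1, nmax + 1):
        full = 4**n + 4 ** (n + 2)
        zqc = zqc_dimension(n) + zqc_dimension(n + 2)
        rows.append(
            {
                "n_substrate_spins": n,
                "dim_full": full,
                "dim_zqc": zqc,
                "ratio": full / zqc,
                "sqrt_pi_n": math.sqrt(math.pi * n),
            }
        )
    return rows
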