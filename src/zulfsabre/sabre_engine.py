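"""Assembly and integration of the SABRE master equation.

The coupled equations for the free substrate (S) and the transient complex
(C = substrate + two hydrides) read, per effective-spin configuration,

    d rho_S / dt = (L_S - Wa) rho_S + kd * TrH2 rho_C
    d rho_C / dt = (L_C - kd) rho_C + Wa * Kron rho_S

with L = -i H^^ + Gamma^^ the Liouvillian, kd the substrate dissociation
rate constant, Wa = kd * [C]/[S] the association rate, TrH2 the partial
trace over the hydrides and Kron the attachment of a fresh parahydrogen
singlet.  Starting from the fully unpolarized state (identities weighted by
the concentration fractions), the block vector (rho_S; rho_C) is propagated
with the action of the matrix exponential per constant-field segment.

Three state representations solve the same equations:

    full       -- every spin-1/2 explicit, no reduction (validation oracle)
    k_reduced  -- equivalence groups replaced by effective spins K
    zqc        -- k_reduced plus restriction to the zero-quantum subspaces

Per-configuration observables are normalized expectations
Tr{O rho_S}/Tr{rho_S}; physical observables are their statistical averages
over configurations with the exact weights g_{K1} g_{K2} ...
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import expm_multiply

from .exchange import kron_map, partial_trace_map, project_exchange, singlet_state
from .hamiltonian import build_hamiltonian, commutation_superoperator
from .operators import spin_matrices, embed
from .relaxation import build_relaxation_superoperator, correlated_group_spec
from .spin_system import (
    EffectiveConfig,
    SpinSystem,
    SpinSystemError,
    enumerate_configs,
    reduce_system,
    validate_system,
)
from .zqc import ZqcIndex, project_superoperator

__all__ = [
    "SabreModel",
    "SabreState",
    "RepSpaces",
    "assemble_generator",
    "initial_state",
    "propagate",
    "substrate_observable_vector",
    "polarizations",
    "field_scan",
    "average_configs",
    "solve",
]

REPRESENTATIONS = ("full", "k_reduced", "zqc")


@dataclass(frozen=True)
class SabreModel:
    """Substrate + complex spin systems with linear exchange kinetics.

    The complex must list the substrate nuclei first (same labels, isotopes
    and gammas; J and T1 values may differ between free and bound forms)
    followed by exactly two hydride spins.  Equivalence groups must be
    identical in both systems.  cs = [C]/[S]; Wa = kd * cs.
    """

    substrate: SpinSystem
    complex: SpinSystem
    kd: float
    cs: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise SpinSystemError(f"kd must be positive, got {self.kd}")
        if not self.cs > 0:
            raise SpinSystemError(f"[C]/[S] must be positive, got {self.cs}")
        validate_system(self.substrate)
        validate_system(self.complex)
        ns = len(self.substrate.nuclei)
        if len(self.complex.nuclei) != ns + 2:
            raise SpinSystemError(
                "complex must contain the substrate nuclei plus two hydrides"
            )
        for s_nuc, c_nuc in zip(self.substrate.nuclei, self.complex.nuclei[:ns]):
            if s_nuc.label != c_nuc.label:
                raise SpinSystemError(
                    f"complex nucleus order must match substrate: "
                    f"{c_nuc.label!r} vs {s_nuc.label!r}"
                )
            if s_nuc.isotope != c_nuc.isotope or s_nuc.gamma != c_nuc.gamma:
                raise SpinSystemError(
                    f"nucleus {s_nuc.label!r} differs in isotope/gamma between "
                    "substrate and complex"
                )
        for h in self.complex.nuclei[ns:]:
            if h.spin != 0.5:
                raise SpinSystemError(f"hydride {h.label!r} must be spin-1/2")
        sub_groups = {g.name: tuple(g.members) for g in self.substrate.groups}
        cx_groups = {g.name: tuple(g.members) for g in self.complex.groups}
        if {k: v for k, v in sub_groups.items()} != cx_groups:
            raise SpinSystemError(
                "equivalence groups must be identical in substrate and complex"
            )

    @property
    def wa(self) -> float:
        return self.kd * self.cs

    @property
    def hydride_labels(self) -> tuple[str, str]:
        return tuple(n.label for n in self.complex.nuclei[-2:])

    def configs(self) -> list[EffectiveConfig]:
        return enumerate_configs(self.substrate)


def _strip_groups(system: SpinSystem) -> SpinSystem:
    """Unreduced view: keep every physical spin, apply group T1 to members."""
    by_member = {m: g for g in system.groups for m in g.members}
    nuclei = tuple(
        replace(n, t1=by_member[n.label].t1)
        if n.label in by_member and by_member[n.label].t1 is not None
        else n
        for n in system.nuclei
    )
    return SpinSystem(nuclei=nuclei, j_table=dict(system.j_table), groups=())


@dataclass(frozen=True)
class RepSpaces:
    """Reduced substrate/complex systems and (for zqc) the subspace indices."""

    representation: str
    red_substrate: SpinSystem
    red_complex: SpinSystem
    zqc_s: ZqcIndex | None
    zqc_c: ZqcIndex | None

    @property
    def dim_s(self) -> int:
        return self.zqc_s.dim if self.zqc_s is not None else self.red_substrate.hilbert_dim**2

    @property
    def dim_c(self) -> int:
        return self.zqc_c.dim if self.zqc_c is not None else self.red_complex.hilbert_dim**2

    @property
    def dim(self) -> int:
        return self.dim_s + self.dim_c


def rep_spaces(model: SabreModel, config: EffectiveConfig, representation: str) -> RepSpaces:
    if representation not in REPRESENTATIONS:
        raise SpinSystemError(f"unknown representation {representation!r}")
    if representation == "full":
        red_s = _strip_groups(model.substrate)
        red_c = _strip_groups(model.complex)
    else:
        red_s = config.reduced_system
        order = list(red_s.labels) + list(model.hydride_labels)
        red_c = reduce_system(model.complex, config.k_values, site_order=order)
    zqc_s = ZqcIndex.of(red_s) if representation == "zqc" else None
    zqc_c = ZqcIndex.of(red_c) if representation == "zqc" else None
    return RepSpaces(representation, red_s, red_c, zqc_s, zqc_c)


@dataclass
class SabreState:
    """Stacked Liouville vector (rho_S part; rho_C part) in one representation."""

    vector: np.ndarray
    spaces: RepSpaces
    config: EffectiveConfig

    @property
    def rho_s_vec(self) -> np.ndarray:
        return self.vector[: self.spaces.dim_s]

    @property
    def rho_c_vec(self) -> np.ndarray:
        return self.vector[self.spaces.dim_s:]

    def rho_s(self) -> np.ndarray:
        """Free-substrate density matrix (embedded back to full space if ZQC)."""
        d = self.spaces.red_substrate.hilbert_dim
        v = (
            self.spaces.zqc_s.scatter(self.rho_s_vec)
            if self.spaces.zqc_s is not None
            else self.rho_s_vec
        )
        return v.reshape(d, d)

    def rho_c(self) -> np.ndarray:
        d = self.spaces.red_complex.hilbert_dim
        v = (
            self.spaces.zqc_c.scatter(self.rho_c_vec)
            if self.spaces.zqc_c is not None
            else self.rho_c_vec
        )
        return v.reshape(d, d)


# ----------------------------------------------------------------------
# generator assembly
# ----------------------------------------------------------------------

def _liouvillian(
    system: SpinSystem, b0: float, unreduced_source: SpinSystem | None
) -> sp.csr_matrix:
    h = build_hamiltonian(system, b0)
    hh = commutation_superoperator(h)
    if unreduced_source is not None and unreduced_source.groups:
        gamma = build_relaxation_superoperator(system, correlated_group_spec(unreduced_source))
    else:
        gamma = build_relaxation_superoperator(system)
    return (-1j * hh + gamma).tocsr()


def assemble_generator(
    model: SabreModel,
    config: EffectiveConfig,
    b0: float,
    representation: str = "zqc",
    spaces: RepSpaces | None = None,
) -> tuple[sp.csr_matrix, RepSpaces]:
    """Block generator of the coupled SABRE master equation at field b0.

    [[L_S - Wa,  kd * TrH2], [Wa * Kron, L_C - kd]], in the requested
    representation (projected onto the ZQC subspaces for 'zqc').
    """
    if spaces is None:
        spaces = rep_spaces(model, config, representation)
    full_rep = spaces.representation == "full"
    ls = _liouvillian(spaces.red_substrate, b0, model.substrate if full_rep else None)
    lc = _liouvillian(spaces.red_complex, b0, model.complex if full_rep else None)
    ds = spaces.red_substrate.hilbert_dim
    a_s = ls - model.wa * sp.identity(ds**2, format="csr", dtype=complex)
    a_c = lc - model.kd * sp.identity((4 * ds) ** 2, format="csr", dtype=complex)
    tr = partial_trace_map(ds)
    kr = kron_map(ds, singlet_state())
    if spaces.representation == "zqc":
        a_s = project_superoperator(a_s, spaces.zqc_s, spaces.zqc_s)
        a_c = project_superoperator(a_c, spaces.zqc_c, spaces.zqc_c)
        tr, kr = project_exchange(tr, kr, spaces.zqc_s, spaces.zqc_c)
    gen = sp.bmat(
        [[a_s, model.kd * tr], [model.wa * kr, a_c]], format="csr", dtype=complex
    )
    return gen, spaces


def initial_state(
    model: SabreModel,
    config: EffectiveConfig,
    representation: str = "zqc",
    spaces: RepSpaces | None = None,
) -> SabreState:
    """Fully unpolarized initial state: normalized identities with
    concentration prefactors, Tr rho_S = 1/(1+cs), Tr rho_C = cs/(1+cs).
    """
    if spaces is None:
        spaces = rep_spaces(model, config, representation)
    ds = spaces.red_substrate.hilbert_dim
    dc = spaces.red_complex.hilbert_dim
    vs = np.eye(ds, dtype=complex).ravel() / (ds * (1.0 + model.cs))
    vc = np.eye(dc, dtype=complex).ravel() * (model.cs / (dc * (1.0 + model.cs)))
    if spaces.representation == "zqc":
        vs = spaces.zqc_s.gather(vs)
        vc = spaces.zqc_c.gather(vc)
    return SabreState(vector=np.concatenate([vs, vc]), spaces=spaces, config=config)


def propagate(
    generator: sp.spmatrix, state: SabreState, duration: float
) -> SabreState:
    """Advance the state by exp(generator * duration) (Krylov/expm action)."""
    if duration < 0:
        raise SpinSystemError("duration must be non-negative")
    if duration == 0.0:
        return state
    vec = expm_multiply(generator * duration, state.vector)
    if not np.all(np.isfinite(vec)):
        raise FloatingPointError(
            f"non-finite state after propagation (dim {state.spaces.dim}, "
            f"duration {duration} s)"
        )
    return SabreState(vector=vec, spaces=state.spaces, config=state.config)


# ----------------------------------------------------------------------
# observables
# ----------------------------------------------------------------------

def observable_sites(model: SabreModel) -> list[str]:
    """Reporting labels: non-equivalent substrate nuclei, then group names."""
    grouped = model.substrate.grouped_labels()
    out = [n.label for n in model.substrate.nuclei if n.label not in grouped]
    out += [g.name for g in model.substrate.groups]
    return out


def substrate_observable_vector(
    spaces: RepSpaces, site: str, model: SabreModel
) -> np.ndarray:
    """Row vector w such that w . rho_S_vec = Tr{O rho_S} for the per-spin
    z polarization of the named site (group sites: Kz / P per proton).
    """
    red = spaces.red_substrate
    group = next((g for g in model.substrate.groups if g.name == site), None)
    d = red.hilbert_dim
    op = sp.csr_matrix((d, d), dtype=complex)
    if spaces.representation == "full" and group is not None:
        for member in group.members:
            i = red.labels.index(member)
            op = op + embed(spin_matrices(0.5)["Iz"], i, red.dims)
        op = op / group.size
    else:
        i = red.labels.index(site)
        op = embed(spin_matrices(red.spins[i])["Iz"], i, red.dims)
        if group is not None:
            op = op / group.size
    w = np.asarray(op.T.todense()).ravel()
    if spaces.zqc_s is not None:
        w = spaces.zqc_s.gather(w)
    return w


def _trace_vector(spaces: RepSpaces, part: str) -> np.ndarray:
    d = (spaces.red_substrate if part == "s" else spaces.red_complex).hilbert_dim
    w = np.eye(d, dtype=complex).ravel()
    idx = spaces.zqc_s if part == "s" else spaces.zqc_c
    return idx.gather(w) if idx is not None else w


def polarizations(state: SabreState, model: SabreModel) -> dict[str, float]:
    """Normalized per-site z polarizations of the free substrate, Eq-(60)-style:
    Tr{Iz rho_S} / Tr{rho_S} for this configuration."""
    tr_s = np.dot(_trace_vector(state.spaces, "s"), state.rho_s_vec)
    out = {}
    for site in observable_sites(model):
        w = substrate_observable_vector(state.spaces, site, model)
        out[site] = float(np.real(np.dot(w, state.rho_s_vec) / tr_s))
    return out


def average_configs(df: pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    """Weight-average per-config polarizations over effective-spin configs.

    Expects long-format columns (B0_T, nucleus, config, weight, polarization);
    weights must sum to 1 for every (field, nucleus).
    """
    def _avg(group: pd.DataFrame) -> float:
        wsum = group["weight"].sum()
        if abs(wsum - 1.0) > atol:
            raise SpinSystemError(f"config weights sum to {wsum}, expected 1")
        return float((group["weight"] * group["polarization"]).sum())

    out = (
        df.groupby(["B0_T", "nucleus"], sort=False)
        .apply(_avg, include_groups=False)
        .rename("polarization")
        .reset_index()
    )
    return out


def field_scan(
    model: SabreModel,
    fields: list[float],
    tpol: float,
    representation: str = "zqc",
) -> pd.DataFrame:
    """Per-nucleus substrate polarization after tpol seconds at each field.

    Returns long-format rows (B0_T, nucleus, config, weight, polarization),
    one per effective-spin configuration; use average_configs for the
    physical (weight-averaged) observable.
    """
    if len(fields) == 0:
        raise SpinSystemError("field list must not be empty")
    configs = model.configs() if representation != "full" else model.configs()[:1]
    rows = []
    for cfg in configs:
        weight = 1.0 if representation == "full" else float(cfg.weight)
        spaces = rep_spaces(model, cfg, representation)
        for b0 in fields:
            gen, _ = assemble_generator(model, cfg, b0, representation, spaces=spaces)
            state = propagate(gen, initial_state(model, cfg, representation, spaces=spaces), tpol)
            for site, pol in polarizations(state, model).items():
                rows.append(
                    {
                        "B0_T": float(b0),
                        "nucleus": site,
                        "config": cfg.label() if representation != "full" else "full",
                        "weight": weight,
                        "polarization": pol,
                    }
                )
    return pd.DataFrame(rows)


def solve(
    model: SabreModel, b0: float, tpol: float, representation: str = "zqc"
) -> dict[str, float]:
    """Weight-averaged per-site substrate polarizations after tpol at field b0."""
    df = field_scan(model, [b0], tpol, representation)
    avg = average_configs(df)
    return dict(zip(avg["nucleus"], avg["polarization"]))
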