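"""Spin-system descriptions and the effective-spin decomposition.

A molecule is described by an ordered list of nuclei, a symmetric J-coupling
table (Hz) and, optionally, groups of magnetically equivalent spin-1/2 nuclei
(e.g. the three protons of a methyl group).  Magnetic equivalence means every
nucleus outside the group couples identically to all group members, which
allows the group of P spins to be replaced by a single *effective* spin K,
with K running from P/2 down to 0 (P even) or 1/2 (P odd).  The physical
ensemble is then a statistical mixture over the allowed K values with weights

    g_K = (2K + 1) * mu_K / 2**P,
    mu_K = (2K + 1) / (P/2 + K + 1) * C(P, P/2 - K),

where mu_K is the multiplicity of total spin K in the product of P spin-1/2
representations.  The weights are exact rationals and sum to one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from itertools import product as _iproduct

import numpy as np

__all__ = [
    "GAMMA_RAD_PER_T",
    "Nucleus",
    "EquivalenceGroup",
    "SpinSystem",
    "EffectiveConfig",
    "SpinSystemError",
    "EquivalenceError",
    "validate_system",
    "multiplicity",
    "statistical_weight",
    "allowed_k_values",
    "reduce_system",
    "enumerate_configs",
    "random_small",
]

#: Gyromagnetic ratios in rad s^-1 T^-1 (standard physical constants).
GAMMA_RAD_PER_T: dict[str, float] = {
    "1H": 267.522_187_08e6,
    "2H": 41.066e6,
    "13C": 67.2828e6,
    "15N": -27.116e6,
    "19F": 251.815e6,
    "31P": 108.291e6,
}

#: Relative tolerance for "identical" external couplings within a group.
EQUIVALENCE_RTOL = 1e-9


class SpinSystemError(ValueError):
    """Structural problem in a spin-system description."""


class EquivalenceError(SpinSystemError):
    """A declared equivalence group violates magnetic equivalence."""


def _check_half_integer(s, name: str = "spin") -> int:
    """Return 2*s as an int, raising if s is not a non-negative half-integer."""
    s2 = 2 * s
    if abs(s2 - round(s2)) > 1e-12 or s < 0:
        raise SpinSystemError(f"{name} must be a non-negative half-integer, got {s}")
    return int(round(s2))


@dataclass(frozen=True)
class Nucleus:
    """One spin site: a physical spin-1/2 nucleus or an effective spin K.

    gamma is in rad s^-1 T^-1 (may be negative); t1 is the longitudinal
    relaxation time in seconds, or None for no relaxation on this site.
    shift_ppm is an isotropic chemical shift added to the Zeeman term.
    """

    label: str
    isotope: str
    gamma: float
    spin: float = 0.5
    t1: float | None = None
    shift_ppm: float = 0.0

    def __post_init__(self) -> None:
        # spin 0 is allowed: a K=0 effective spin is a one-dimensional site
        _check_half_integer(self.spin, f"spin of {self.label!r}")
        if not math.isfinite(self.gamma):
            raise SpinSystemError(f"gamma of {self.label!r} is not finite")
        if self.t1 is not None and not self.t1 > 0:
            raise SpinSystemError(f"t1 of {self.label!r} must be positive or None")

    @property
    def dim(self) -> int:
        return _check_half_integer(self.spin) + 1


@dataclass(frozen=True)
class EquivalenceGroup:
    """A set of P >= 2 magnetically equivalent spin-1/2 nuclei.

    All members must share isotope, gamma and the group T1; every external
    nucleus must couple identically to each member.
    """

    name: str
    members: tuple[str, ...]
    t1: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if len(self.members) < 2:
            raise SpinSystemError(f"group {self.name!r} needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise SpinSystemError(f"group {self.name!r} has repeated members")

    @property
    def size(self) -> int:
        return len(self.members)


def _canonical_j(
    nuclei: tuple[Nucleus, ...], j_table: dict
) -> dict[tuple[str, str], float]:
    order = {n.label: i for i, n in enumerate(nuclei)}
    out: dict[tuple[str, str], float] = {}
    for (a, b), j in j_table.items():
        if a not in order or b not in order:
            raise SpinSystemError(f"J entry references unknown label: ({a}, {b})")
        if a == b:
            if j != 0.0:
                raise SpinSystemError(f"diagonal J entry for {a!r} must be zero")
            continue
        key = (a, b) if order[a] < order[b] else (b, a)
        if key in out and not np.isclose(out[key], float(j), rtol=1e-12, atol=0.0):
            raise SpinSystemError(f"asymmetric J table at pair {key}")
        out[key] = float(j)
    return out


@dataclass(frozen=True)
class SpinSystem:
    """An ordered collection of spin sites with scalar couplings and groups."""

    nuclei: tuple[Nucleus, ...]
    j_table: dict[tuple[str, str], float] = field(default_factory=dict)
    groups: tuple[EquivalenceGroup, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.nuclei) == 0:
            raise SpinSystemError("spin system has no nuclei")
        labels = [n.label for n in self.nuclei]
        if len(set(labels)) != len(labels):
            raise SpinSystemError("duplicate nucleus labels")
        object.__setattr__(self, "j_table", _canonical_j(self.nuclei, self.j_table))

    # -- basic queries -------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nuclei]

    @property
    def spins(self) -> list[float]:
        return [n.spin for n in self.nuclei]

    @property
    def dims(self) -> list[int]:
        return [n.dim for n in self.nuclei]

    @property
    def hilbert_dim(self) -> int:
        return int(np.prod(self.dims))

    def nucleus(self, label: str) -> Nucleus:
        for n in self.nuclei:
            if n.label == label:
                return n
        raise KeyError(label)

    def j(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        order = {n.label: i for i, n in enumerate(self.nuclei)}
        key = (a, b) if order[a] < order[b] else (b, a)
        return self.j_table.get(key, 0.0)

    def grouped_labels(self) -> set[str]:
        return {m for g in self.groups for m in g.members}


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def validate_system(system: SpinSystem) -> SpinSystem:
    """Check all structural and magnetic-equivalence invariants.

    Returns the system unchanged if valid; raises SpinSystemError or
    EquivalenceError (naming the offending pair) otherwise.
    """
    seen: set[str] = set()
    for g in system.groups:
        for m in g.members:
            if m not in system.labels:
                raise SpinSystemError(f"group {g.name!r} member {m!r} not in system")
            if m in seen:
                raise SpinSystemError(f"nucleus {m!r} belongs to more than one group")
            seen.add(m)
        members = [system.nucleus(m) for m in g.members]
        ref = members[0]
        for n in members[1:]:
            if n.isotope != ref.isotope or n.gamma != ref.gamma:
                raise EquivalenceError(
                    f"group {g.name!r}: members {ref.label!r} and {n.label!r} "
                    "differ in isotope/gamma"
                )
            if n.spin != 0.5 or ref.spin != 0.5:
                raise EquivalenceError(
                    f"group {g.name!r}: only spin-1/2 members are supported"
                )
            if n.shift_ppm != ref.shift_ppm:
                raise EquivalenceError(
                    f"group {g.name!r}: members {ref.label!r} and {n.label!r} "
                    "differ in chemical shift"
                )
        # every external nucleus must couple identically to all members
        for ext in system.labels:
            if ext in g.members:
                continue
            j0 = system.j(ext, g.members[0])
            for m in g.members[1:]:
                jm = system.j(ext, m)
                scale = max(abs(j0), abs(jm), 1.0)
                if abs(jm - j0) > EQUIVALENCE_RTOL * scale:
                    raise EquivalenceError(
                        f"group {g.name!r} is not magnetically equivalent: "
                        f"J({ext},{g.members[0]})={j0} Hz but J({ext},{m})={jm} Hz"
                    )
    return system


# ----------------------------------------------------------------------
# multiplicities and statistical weights
# ----------------------------------------------------------------------

def allowed_k_values(P: int) -> list[Fraction]:
    """Allowed total spins of P equivalent spin-1/2 nuclei, descending from P/2.

    The minimum is 0 for even P and 1/2 for odd P.
    """
    if P < 1:
        raise SpinSystemError(f"group size must be >= 1, got {P}")
    top = Fraction(P, 2)
    n = P // 2 + 1
    return [top - i for i in range(n)]


def _k2(P: int, K) -> int:
    k2 = _check_half_integer(K, "K")
    if k2 > P or (P - k2) % 2 != 0 or (P % 2 == 0) != (k2 % 2 == 0):
        raise SpinSystemError(f"K={K} is not an allowed total spin for P={P}")
    return k2


def multiplicity(P: int, K) -> int:
    """Number of times total spin K occurs in the product of P spin-1/2 spaces."""
    k2 = _k2(P, K)
    mu = Fraction(k2 + 1) / Fraction(P + k2 + 2, 2) * math.comb(P, (P - k2) // 2)
    assert mu.denominator == 1
    return int(mu)


def statistical_weight(P: int, K) -> Fraction:
    """Exact statistical weight g_K = (2K+1) mu_K / 2^P of the K subspace."""
    k2 = _k2(P, K)
    return Fraction((k2 + 1) * multiplicity(P, K), 2**P)


# ----------------------------------------------------------------------
# effective-spin reduction
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class EffectiveConfig:
    """One assignment of total spin K to each equivalence group.

    weight is the exact product of per-group statistical weights; the
    reduced_system replaces each group by a single effective nucleus of
    spin K carrying the group's gamma, T1 and common external couplings.
    """

    k_values: dict[str, Fraction]
    weight: Fraction
    reduced_system: SpinSystem

    def label(self) -> str:
        if not self.k_values:
            return "-"
        return ",".join(f"{g}={k}" for g, k in self.k_values.items())


def reduce_system(
    system: SpinSystem,
    k_values: dict[str, Fraction],
    site_order: list[str] | None = None,
) -> SpinSystem:
    """Replace each equivalence group by one effective spin-K nucleus.

    Default site order: non-equivalent nuclei in declaration order, then one
    effective nucleus per group in group-declaration order.  site_order may
    override this with an explicit list of labels (nucleus labels for
    non-equivalent sites, group names for effective sites).
    """
    validate_system(system)
    if set(k_values) != {g.name for g in system.groups}:
        raise SpinSystemError(
            f"k_values keys {sorted(k_values)} do not match group names"
        )
    grouped = system.grouped_labels()
    by_group = {g.name: g for g in system.groups}

    new_nuclei: list[Nucleus] = []
    default_order = [n.label for n in system.nuclei if n.label not in grouped]
    default_order += [g.name for g in system.groups]
    order = list(site_order) if site_order is not None else default_order
    if sorted(order) != sorted(default_order):
        raise SpinSystemError("site_order must permute non-equivalent labels and group names")

    def site_nucleus(name: str) -> Nucleus:
        if name in by_group:
            g = by_group[name]
            proto = system.nucleus(g.members[0])
            K = k_values[g.name]
            return Nucleus(
                label=g.name,
                isotope=proto.isotope,
                gamma=proto.gamma,
                spin=float(K),
                t1=g.t1 if g.t1 is not None else proto.t1,
                shift_ppm=proto.shift_ppm,
            )
        return system.nucleus(name)

    new_nuclei = [site_nucleus(name) for name in order]

    def representative(name: str) -> str:
        return by_group[name].members[0] if name in by_group else name

    j_new: dict[tuple[str, str], float] = {}
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            j = system.j(representative(a), representative(b))
            if j != 0.0:
                j_new[(a, b)] = j

    return SpinSystem(nuclei=tuple(new_nuclei), j_table=j_new, groups=())


def enumerate_configs(system: SpinSystem) -> list[EffectiveConfig]:
    """All effective-spin configurations of a validated system.

    Cartesian product of allowed K per group; each configuration carries the
    exact product weight and the corresponding reduced system.  A system
    without groups yields a single configuration of weight 1 whose reduced
    system is the system itself (groups stripped).
    """
    validate_system(system)
    if not system.groups:
        bare = replace(system, groups=())
        return [EffectiveConfig(k_values={}, weight=Fraction(1), reduced_system=bare)]
    names = [g.name for g in system.groups]
    choices = [allowed_k_values(g.size) for g in system.groups]
    configs = []
    for combo in _iproduct(*choices):
        kv = dict(zip(names, combo))
        w = Fraction(1)
        for g, K in zip(system.groups, combo):
            w *= statistical_weight(g.size, K)
        configs.append(
            EffectiveConfig(k_values=kv, weight=w, reduced_system=reduce_system(system, kv))
        )
    assert sum(c.weight for c in configs) == 1
    return configs


# ----------------------------------------------------------------------
# random test systems
# ----------------------------------------------------------------------

def random_small(
    n_spins: int,
    seed: int,
    n_group: int = 0,
    isotopes: tuple[str, ...] = ("1H", "13C", "15N"),
    with_t1: bool = True,
) -> SpinSystem:
    """Random small spin system for property tests.

    n_spins individual spin-1/2 nuclei plus, if n_group >= 2, one group of
    n_group magnetically equivalent protons (identical external couplings by
    construction).  Couplings are O(1-150) Hz, T1 values O(1-20) s.
    """
    rng = np.random.default_rng(seed)
    nuclei = []
    for i in range(n_spins):
        iso = isotopes[rng.integers(len(isotopes))]
        nuclei.append(
            Nucleus(
                label=f"S{i}",
                isotope=iso,
                gamma=GAMMA_RAD_PER_T[iso],
                t1=float(rng.uniform(1.0, 20.0)) if with_t1 else None,
            )
        )
    groups: tuple[EquivalenceGroup, ...] = ()
    glabels: list[str] = []
    if n_group >= 2:
        glabels = [f"G{i}" for i in range(n_group)]
        for lab in glabels:
            nuclei.append(
                Nucleus(
                    label=lab,
                    isotope="1H",
                    gamma=GAMMA_RAD_PER_T["1H"],
                    t1=float(rng.uniform(1.0, 20.0)) if with_t1 else None,
                )
            )
        groups = (
            EquivalenceGroup(
                name="Geq",
                members=tuple(glabels),
                t1=float(rng.uniform(1.0, 20.0)) if with_t1 else None,
            ),
        )
    j: dict[tuple[str, str], float] = {}
    for i in range(n_spins):
        for k in range(i + 1, n_spins):
            j[(f"S{i}", f"S{k}")] = float(rng.uniform(-20.0, 150.0))
        if glabels:
            jg = float(rng.uniform(-20.0, 150.0))
            for lab in glabels:
                j[(f"S{i}", lab)] = jg
    return validate_system(SpinSystem(nuclei=tuple(nuclei), j_table=j, groups=groups))
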