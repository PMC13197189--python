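"""Shared fixtures: small SABRE models built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from zulfsabre import SabreModel
from zulfsabre.spin_system import (
    GAMMA_RAD_PER_T,
    EquivalenceGroup,
    Nucleus,
    SpinSystem,
    random_small,
)


def attach_hydrides(
    substrate: SpinSystem,
    j_to_hydride: dict[str, float] | None = None,
    jhh: float = -10.0,
    t1_hydride: float = 1.0,
    bound_t1_scale: float = 1.0,
) -> SpinSystem:
    """Build a complex system: substrate sites (bound-form T1) + two hydrides.

    j_to_hydride maps substrate labels (or group names, applied to every
    member) to the coupling with the first hydride HA.
    """
    gh = GAMMA_RAD_PER_T["1H"]
    nuclei = []
    for n in substrate.nuclei:
        t1 = n.t1 * bound_t1_scale if n.t1 is not None else None
        nuclei.append(Nucleus(n.label, n.isotope, n.gamma, n.spin, t1, n.shift_ppm))
    nuclei.append(Nucleus("HYA", "1H", gh, 0.5, t1_hydride))
    nuclei.append(Nucleus("HYB", "1H", gh, 0.5, t1_hydride))
    j = dict(substrate.j_table)
    j[("HYA", "HYB")] = jhh
    groups = []
    for g in substrate.groups:
        t1 = g.t1 * bound_t1_scale if g.t1 is not None else None
        groups.append(EquivalenceGroup(g.name, g.members, t1))
    by_group = {g.name: g for g in substrate.groups}
    for label, jval in (j_to_hydride or {}).items():
        targets = by_group[label].members if label in by_group else (label,)
        for t in targets:
            j[(t, "HYA")] = jval
    return SpinSystem(nuclei=tuple(nuclei), j_table=j, groups=tuple(groups))


def make_toy_model(
    j_sub: float = -5.0,
    j_nh: float = -15.0,
    jhh: float = -10.0,
    kd: float = 10.0,
    cs: float = 0.1,
    with_group: bool = True,
) -> SabreModel:
    """15N + two equivalent protons (CH2) substrate; 5-spin complex."""
    gh, gn = GAMMA_RAD_PER_T["1H"], GAMMA_RAD_PER_T["15N"]
    nuclei = (
        Nucleus("N1", "15N", gn, 0.5, 10.0),
        Nucleus("Ha", "1H", gh),
        Nucleus("Hb", "1H", gh),
    )
    j = {("N1", "Ha"): j_sub, ("N1", "Hb"): j_sub}
    groups = (EquivalenceGroup("CH2", ("Ha", "Hb"), 6.0),) if with_group else ()
    if not with_group:
        j["Ha", "Hb"] = 7.0  # inequivalent pair needs an explicit coupling
    substrate = SpinSystem(nuclei=nuclei, j_table=j, groups=groups)
    complex_ = attach_hydrides(
        substrate, {"N1": j_nh}, jhh=jhh, t1_hydride=1.0, bound_t1_scale=0.3
    )
    return SabreModel(substrate=substrate, complex=complex_, kd=kd, cs=cs, name="toy")


def make_pair_model(j_ch: float = 25.0, kd: float = 20.0, cs: float = 0.2) -> SabreModel:
    """Two-spin heteronuclear (13C-1H) substrate; 4-spin complex."""
    gh, gc = GAMMA_RAD_PER_T["1H"], GAMMA_RAD_PER_T["13C"]
    substrate = SpinSystem(
        nuclei=(Nucleus("C1", "13C", gc, 0.5, 20.0), Nucleus("H1", "1H", gh, 0.5, 15.0)),
        j_table={("C1", "H1"): j_ch},
    )
    complex_ = attach_hydrides(
        substrate, {"C1": -12.0, "H1": 2.0}, jhh=-10.0, bound_t1_scale=0.25
    )
    return SabreModel(substrate=substrate, complex=complex_, kd=kd, cs=cs, name="pair")


def random_sabre_model(n_sub: int, seed: int, n_group: int = 0) -> SabreModel:
    """Random small SABRE model with group-consistent hydride couplings."""
    rng = np.random.default_rng(seed + 1000)
    substrate = random_small(n_sub, seed, n_group=n_group)
    j_h = {}
    for n in substrate.nuclei:
        if n.label.startswith("S"):
            j_h[n.label] = float(rng.uniform(-25.0, 5.0))
    if substrate.groups:
        j_h[substrate.groups[0].name] = float(rng.uniform(-25.0, 5.0))
    complex_ = attach_hydrides(substrate, j_h, jhh=float(rng.uniform(-12.0, -6.0)))
    return SabreModel(
        substrate=substrate,
        complex=complex_,
        kd=float(rng.uniform(5.0, 50.0)),
        cs=float(rng.uniform(0.05, 0.5)),
        name=f"random{n_sub}-{seed}",
    )


@pytest.fixture(scope="session")
def acetonitrile():
    from zulfsabre import acetonitrile_15N13C2

    return acetonitrile_15N13C2()


@pytest.fixture(scope="session")
def butyronitrile():
    from zulfsabre import butyronitrile_15N13C4

    return butyronitrile_15N13C4()


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_model()


@pytest.fixture(scope="session")
def pair_model():
    return make_pair_model()
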