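"""Spin-system validation, effective-spin multiplicities and weights."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zulfsabre import (
    EquivalenceError,
    EquivalenceGroup,
    Nucleus,
    SpinSystem,
    SpinSystemError,
    allowed_k_values,
    enumerate_configs,
    multiplicity,
    random_small,
    reduce_system,
    statistical_weight,
    validate_system,
)
from zulfsabre.spin_system import GAMMA_RAD_PER_T

GH = GAMMA_RAD_PER_T["1H"]


@pytest.mark.parametrize(
    "p, k, mu",
    [
        (3, Fraction(1, 2), 2),
        (2, 1, 1),
        (2, 0, 1),
        (1, Fraction(1, 2), 1),
        (4, 2, 1),
        (4, 1, 3),
        (4, 0, 2),
    ],
)
def test_multiplicity_values(p, k, mu):
    assert multiplicity(p, k) == mu


@pytest.mark.parametrize(
    "p, k, g",
    [
        (3, Fraction(3, 2), Fraction(1, 2)),
        (3, Fraction(1, 2), Fraction(1, 2)),
        (2, 1, Fraction(3, 4)),
        (2, 0, Fraction(1, 4)),
    ],
)
def test_statistical_weight_values(p, k, g):
    assert statistical_weight(p, k) == g


@pytest.mark.parametrize("p", range(1, 11))
def test_multiplicity_sum_rule(p):
    """Sum of (2K+1) mu_K over allowed K recovers the 2^P product dimension,
    and the statistical weights sum to one exactly."""
    ks = allowed_k_values(p)
    total = sum((2 * k + 1) * multiplicity(p, k) for k in ks)
    assert total == 2**p
    assert sum(statistical_weight(p, k) for k in ks) == 1


def test_multiplicity_domain_errors():
    with pytest.raises(SpinSystemError):
        multiplicity(3, 1)  # wrong parity
    with pytest.raises(SpinSystemError):
        multiplicity(2, 2)  # K > P/2
    with pytest.raises(SpinSystemError):
        statistical_weight(4, Fraction(5, 2))


def _three_proton_system(j_x_p2=7.0):
    nuclei = (
        Nucleus("X", "13C", GAMMA_RAD_PER_T["13C"], 0.5, 5.0),
        Nucleus("p1", "1H", GH),
        Nucleus("p2", "1H", GH),
        Nucleus("p3", "1H", GH),
    )
    j = {("X", "p1"): 7.0, ("X", "p2"): j_x_p2, ("X", "p3"): 7.0}
    groups = (EquivalenceGroup("CH3", ("p1", "p2", "p3"), 4.0),)
    return SpinSystem(nuclei=nuclei, j_table=j, groups=groups)


def test_equivalence_violation_names_pair():
    """A group whose members see different external couplings is rejected,
    naming the offending coupling pair."""
    with pytest.raises(EquivalenceError, match=r"p2"):
        validate_system(_three_proton_system(j_x_p2=6.0))
    validate_system(_three_proton_system())  # identical couplings accepted


def test_structural_errors():
    with pytest.raises(SpinSystemError):
        SpinSystem(nuclei=())  # no nuclei
    with pytest.raises(SpinSystemError):
        SpinSystem(
            nuclei=(Nucleus("a", "1H", GH), Nucleus("a", "1H", GH))
        )  # duplicate labels
    with pytest.raises(SpinSystemError):
        SpinSystem(nuclei=(Nucleus("a", "1H", GH),), j_table={("a", "a"): 3.0})
    # overlapping groups
    nuclei = tuple(Nucleus(f"h{i}", "1H", GH) for i in range(4))
    sys_ = SpinSystem(
        nuclei=nuclei,
        groups=(
            EquivalenceGroup("g1", ("h0", "h1")),
            EquivalenceGroup("g2", ("h1", "h2")),
        ),
    )
    with pytest.raises(SpinSystemError, match="more than one group"):
        validate_system(sys_)


def test_acetonitrile_fixture_configs(acetonitrile):
    """One CH3 group: two configurations K = 3/2 and 1/2 with equal weights."""
    configs = enumerate_configs(acetonitrile.substrate)
    assert len(configs) == 2
    assert sorted(c.weight for c in configs) == [Fraction(1, 2), Fraction(1, 2)]
    assert {float(k) for c in configs for k in c.k_values.values()} == {1.5, 0.5}
    for c in configs:
        validate_system(c.reduced_system)


def test_butyronitrile_fixture_configs(butyronitrile):
    """Two CH2 + one CH3 group: 8 configurations with the known weight table
    (36/128, 36/128, 12/128 x4, 4/128 x2), summing to one exactly."""
    configs = enumerate_configs(butyronitrile.substrate)
    assert len(configs) == 8
    weights = sorted(c.weight for c in configs)
    assert weights == sorted(
        [
            Fraction(36, 128),
            Fraction(36, 128),
            Fraction(12, 128),
            Fraction(12, 128),
            Fraction(12, 128),
            Fraction(12, 128),
            Fraction(4, 128),
            Fraction(4, 128),
        ]
    )
    assert sum(weights) == 1
    # the heaviest configuration is (K1=1, K2=1, K3=3/2)
    top = max(configs, key=lambda c: (c.weight, str(c.k_values)))
    assert {float(k) for k in top.k_values.values()} == {1.0, 1.5}


def test_group_free_system_single_config():
    sys_ = SpinSystem(
        nuclei=(Nucleus("a", "1H", GH), Nucleus("b", "13C", GAMMA_RAD_PER_T["13C"])),
        j_table={("a", "b"): 5.0},
    )
    configs = enumerate_configs(sys_)
    assert len(configs) == 1
    assert configs[0].weight == 1
    assert configs[0].reduced_system.labels == ["a", "b"]


def test_reduced_system_ordering():
    """Non-equivalent nuclei keep declaration order; effective spins follow."""
    sys_ = _three_proton_system()
    red = reduce_system(sys_, {"CH3": Fraction(3, 2)})
    assert red.labels == ["X", "CH3"]
    assert red.nucleus("CH3").spin == 1.5
    assert red.nucleus("CH3").gamma == GH
    assert red.nucleus("CH3").t1 == 4.0
    assert red.j("X", "CH3") == 7.0
    # explicit site order permutes deterministically
    red2 = reduce_system(sys_, {"CH3": Fraction(1, 2)}, site_order=["CH3", "X"])
    assert red2.labels == ["CH3", "X"]


@settings(derandomize=True, max_examples=20, deadline=None)
@given(
    n=st.integers(min_value=1, max_value=3),
    seed=st.integers(min_value=0, max_value=10_000),
    ngrp=st.sampled_from([0, 2, 3]),
)
def test_random_systems_reduce_and_validate(n, seed, ngrp):
    """Every configuration of a random system carries a valid reduced system
    and the exact weights sum to one."""
    sys_ = random_small(n, seed, n_group=ngrp)
    configs = enumerate_configs(sys_)
    assert sum(c.weight for c in configs) == 1
    for c in configs:
        validate_system(c.reduced_system)
        assert len(c.reduced_system.nuclei) == n + (1 if ngrp else 0)
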