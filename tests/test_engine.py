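"""SABRE master-equation assembly, propagation and representation equivalence."""

import numpy as np
import pytest
import scipy.linalg

from conftest import make_pair_model, make_toy_model, random_sabre_model
from zulfsabre import SabreModel, SpinSystemError, average_configs, field_scan, solve
from zulfsabre.reference import solve_full, solve_k_reduced, solve_zqc
from zulfsabre.sabre_engine import (
    assemble_generator,
    initial_state,
    polarizations,
    propagate,
    rep_spaces,
    _trace_vector,
)
from zulfsabre.spin_system import GAMMA_RAD_PER_T, Nucleus, SpinSystem


def test_model_validation():
    gh = GAMMA_RAD_PER_T["1H"]
    sub = SpinSystem(nuclei=(Nucleus("a", "1H", gh, 0.5, 5.0),))
    good_cx = SpinSystem(
        nuclei=(
            Nucleus("a", "1H", gh, 0.5, 2.0),
            Nucleus("h1", "1H", gh, 0.5, 1.0),
            Nucleus("h2", "1H", gh, 0.5, 1.0),
        ),
        j_table={("a", "h1"): -10.0, ("h1", "h2"): -8.0},
    )
    SabreModel(substrate=sub, complex=good_cx, kd=10.0, cs=0.1)
    with pytest.raises(SpinSystemError):  # missing hydrides
        SabreModel(substrate=sub, complex=sub, kd=10.0, cs=0.1)
    with pytest.raises(SpinSystemError):  # non-positive kinetics
        SabreModel(substrate=sub, complex=good_cx, kd=-1.0, cs=0.1)
    with pytest.raises(SpinSystemError):
        SabreModel(substrate=sub, complex=good_cx, kd=1.0, cs=0.0)


def test_initial_state_traces_and_support(toy_model):
    """Unpolarized start: Tr rho_S = 1/(1+cs), Tr rho_C = cs/(1+cs); the
    state is entirely inside the ZQC subspace and every <Iz> vanishes."""
    m = toy_model
    for rep in ("zqc", "k_reduced", "full"):
        cfg = m.configs()[0]
        st = initial_state(m, cfg, rep)
        rs, rc = st.rho_s(), st.rho_c()
        assert np.isclose(np.trace(rs).real, 1 / (1 + m.cs))
        assert np.isclose(np.trace(rc).real, m.cs / (1 + m.cs))
        assert np.abs(rs - np.diag(np.diag(rs))).max() == 0.0  # diagonal => q=0
        for pol in polarizations(st, m).values():
            assert abs(pol) < 1e-14


def test_trace_functional_is_left_null_vector(toy_model):
    """The global trace functional annihilates the generator: total substrate
    plus complex population is conserved for any state."""
    m = toy_model
    for rep in ("zqc", "full"):
        cfg = m.configs()[0]
        gen, spaces = assemble_generator(m, cfg, 0.5e-6, rep)
        w = np.concatenate([_trace_vector(spaces, "s"), _trace_vector(spaces, "c")])
        assert np.abs(w @ gen).max() < 1e-10


def test_propagate_zero_duration_and_trace_conservation(toy_model):
    m = toy_model
    cfg = m.configs()[0]
    gen, spaces = assemble_generator(m, cfg, 0.5e-6, "zqc")
    st = initial_state(m, cfg, "zqc", spaces=spaces)
    assert propagate(gen, st, 0.0) is st
    st10 = propagate(gen, st, 10.0)
    assert np.isclose(np.trace(st10.rho_s()).real, 1 / (1 + m.cs), atol=1e-10)
    assert np.isclose(np.trace(st10.rho_c()).real, m.cs / (1 + m.cs), atol=1e-10)


def test_propagate_matches_dense_exponential():
    """Krylov action agrees with the dense matrix exponential on a model
    small enough to exponentiate directly."""
    m = make_pair_model()
    cfg = m.configs()[0]
    gen, spaces = assemble_generator(m, cfg, 0.5e-6, "zqc")
    st = initial_state(m, cfg, "zqc", spaces=spaces)
    out = propagate(gen, st, 1.3).vector
    dense = scipy.linalg.expm(gen.toarray() * 1.3) @ st.vector
    assert np.abs(out - dense).max() < 1e-10


def test_density_matrices_stay_physical(toy_model):
    """Hermiticity and positivity of both density matrices over a long horizon."""
    m = toy_model
    cfg = m.configs()[0]
    gen, spaces = assemble_generator(m, cfg, 0.4e-6, "zqc")
    st = propagate(gen, initial_state(m, cfg, "zqc", spaces=spaces), 10.0)
    for rho in (st.rho_s(), st.rho_c()):
        assert np.abs(rho - rho.conj().T).max() < 1e-10
        assert np.linalg.eigvalsh(rho).min() > -1e-10


@pytest.mark.parametrize("seed", [0, 1])
@pytest.mark.parametrize("n_sub", [1, 2])
def test_three_representations_agree_group_free(n_sub, seed):
    """Full-space, K-reduced and ZQC solutions of the same master equation
    agree on every substrate <Iz> to high relative accuracy."""
    m = random_sabre_model(n_sub, seed)
    full = solve_full(m, 0.6e-6, 1.0)
    kred = solve_k_reduced(m, 0.6e-6, 1.0)
    zqc = solve_zqc(m, 0.6e-6, 1.0)
    for site in full:
        scale = max(abs(full[site]), 1e-12)
        assert abs(full[site] - kred[site]) / scale < 1e-8
        assert abs(full[site] - zqc[site]) / scale < 1e-8


@pytest.mark.parametrize("n_group", [2, 3])
def test_three_representations_agree_with_group(n_group):
    """Equivalence groups: the effective-spin mixture reproduces the explicit
    multi-proton calculation, including collective relaxation."""
    m = random_sabre_model(1, seed=7, n_group=n_group)
    full = solve_full(m, 0.5e-6, 1.0)
    kred = solve_k_reduced(m, 0.5e-6, 1.0)
    zqc = solve_zqc(m, 0.5e-6, 1.0)
    for site in full:
        scale = max(abs(full[site]), 1e-12)
        assert abs(full[site] - kred[site]) / scale < 1e-8
        assert abs(full[site] - zqc[site]) / scale < 1e-8


def test_no_transfer_without_hydride_coupling():
    """With all substrate-hydride J zero there is no transfer pathway and the
    substrate stays unpolarized at every field."""
    m = make_toy_model(j_nh=0.0)
    df = field_scan(m, [0.2e-6, 0.5e-6, 1.0e-6], tpol=1.0, representation="zqc")
    assert np.abs(df["polarization"].values).max() < 1e-12


def test_field_scan_and_averaging(toy_model):
    df = field_scan(toy_model, [0.5e-6], tpol=0.5, representation="zqc")
    # one row per (config, site)
    assert len(df) == len(toy_model.configs()) * 2
    avg = average_configs(df)
    assert set(avg["nucleus"]) == {"N1", "CH2"}
    # averaging is the weighted sum of per-config values
    for site in ("N1", "CH2"):
        sub = df[df["nucleus"] == site]
        manual = float((sub["weight"] * sub["polarization"]).sum())
        assert np.isclose(avg[avg["nucleus"] == site]["polarization"].iloc[0], manual)
    with pytest.raises(SpinSystemError):
        field_scan(toy_model, [], tpol=1.0)
    bad = df.copy()
    bad["weight"] = 0.3
    with pytest.raises(SpinSystemError):
        average_configs(bad)


def test_single_config_average_is_identity(pair_model):
    df = field_scan(pair_model, [0.4e-6], tpol=0.5)
    avg = average_configs(df)
    assert np.allclose(
        np.sort(avg["polarization"].values), np.sort(df["polarization"].values)
    )


def test_zqc_generator_dimension(acetonitrile):
    """The assembled ZQC generator for the larger methyl configuration has
    the documented 3034 = 196 + 2838 rows."""
    cfg = next(
        c for c in acetonitrile.configs() if float(list(c.k_values.values())[0]) == 1.5
    )
    spaces = rep_spaces(acetonitrile, cfg, "zqc")
    assert spaces.dim == 3034
    gen, _ = assemble_generator(acetonitrile, cfg, 0.5e-6, "zqc", spaces=spaces)
    assert gen.shape == (3034, 3034)


def test_dimension_cap_refusal(butyronitrile):
    with pytest.raises(SpinSystemError, match="exceeds cap"):
        solve_full(butyronitrile, 0.5e-6, 1.0)
    with pytest.raises(SpinSystemError, match="exceeds cap"):
        solve_k_reduced(butyronitrile, 0.5e-6, 1.0)
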