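"""ZULF observables, free-induction decays and spectra.

The detected ZULF signal is the gamma-weighted total longitudinal
magnetization of the free substrate,

    O_ZULF = sum_l gamma_l Iz_l,

sampled during the detection stage of the two-stage protocol: polarization
build-up for tpol at B0, then continued evolution of the same master
equation (exchange and relaxation stay on) at the residual detection field
B_zulf while <O_ZULF>(t) is recorded on a uniform time grid.  Spectra are
obtained by exponential apodization, zero-filling and a real-input FFT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import expm_multiply

from .operators import embed, spin_matrices
from .sabre_engine import (
    RepSpaces,
    SabreModel,
    SabreState,
    _trace_vector,
    assemble_generator,
    initial_state,
    propagate,
    rep_spaces,
)
from .spin_system import SpinSystem, SpinSystemError
from .zqc import coherence_orders

__all__ = [
    "Fid",
    "Spectrum",
    "UnsupportedObservableError",
    "expectation",
    "zulf_observable",
    "simulate_fid",
    "spectrum",
]


class UnsupportedObservableError(SpinSystemError):
    """Observable has coherence-order components invisible in the ZQC basis."""


@dataclass(frozen=True)
class Fid:
    """Uniformly sampled free-induction decay of <O_ZULF>(t)."""

    times: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) < 2:
            raise SpinSystemError("an FID needs at least two samples")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-15):
            raise SpinSystemError("FID sampling must be uniform")

    @property
    def dwell(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class Spectrum:
    """One-sided frequency-domain spectrum with processing metadata."""

    freq_hz: np.ndarray
    amplitude: np.ndarray
    meta: dict = field(default_factory=dict)


def _observable_vector(observable, spaces: RepSpaces, atol: float = 1e-12) -> np.ndarray:
    """vec(O^T) on the substrate Liouville space, gathered to ZQC if needed.

    Raises UnsupportedObservableError if O has components of nonzero
    coherence order above atol: such components are invisible in the ZQC
    representation and would silently bias the expectation value.
    """
    import scipy.sparse as sp

    o = sp.csr_matrix(observable)
    d = spaces.red_substrate.hilbert_dim
    if o.shape != (d, d):
        raise SpinSystemError(f"observable shape {o.shape} != ({d}, {d})")
    w = np.asarray(o.T.todense()).ravel()
    if spaces.zqc_s is not None:
        q2 = coherence_orders(spaces.red_substrate)
        off = np.abs(w[q2 != 0]).max(initial=0.0)
        if off > atol:
            raise UnsupportedObservableError(
                f"observable has coherence-order components of magnitude {off:.3g} "
                "outside the ZQC subspace"
            )
        w = spaces.zqc_s.gather(w)
    return w


def expectation(observable, state: SabreState) -> float:
    """Normalized per-config expectation Tr{O rho_S} / Tr{rho_S}."""
    w = _observable_vector(observable, state.spaces)
    tr = np.dot(_trace_vector(state.spaces, "s"), state.rho_s_vec)
    return float(np.real(np.dot(w, state.rho_s_vec) / tr))


def zulf_observable(system: SpinSystem):
    """O_ZULF = sum_l gamma_l Iz_l on a reduced system (effective spins carry
    the group gamma, so a group of P protons contributes gamma_H * Kz)."""
    if system.groups:
        raise SpinSystemError("zulf_observable expects a reduced (group-free) system")
    import scipy.sparse as sp

    d = system.hilbert_dim
    op = sp.csr_matrix((d, d), dtype=complex)
    for i, nuc in enumerate(system.nuclei):
        op = op + nuc.gamma * embed(spin_matrices(nuc.spin)["Iz"], i, system.dims)
    return op.tocsr()


def simulate_fid(
    model: SabreModel,
    b0: float,
    tpol: float,
    b_zulf: float,
    t_acq: float,
    dwell: float,
    representation: str = "zqc",
) -> Fid:
    """Two-stage ZULF SABRE protocol: polarize at b0 for tpol, then detect
    <O_ZULF>(t) of the free substrate at b_zulf for t_acq with the full
    master equation (parahydrogen exchange continues during detection).

    The weight-averaged FID over all effective-spin configurations is
    returned; signal units are rad s^-1 T^-1 times dimensionless spin.
    """
    if not dwell > 0 or dwell > t_acq / 2:
        raise SpinSystemError("dwell must be positive and at most t_acq / 2")
    n = int(round(t_acq / dwell)) + 1
    times = np.arange(n) * dwell
    total = np.zeros(n)
    configs = model.configs() if representation != "full" else model.configs()[:1]
    for cfg in configs:
        weight = 1.0 if representation == "full" else float(cfg.weight)
        spaces = rep_spaces(model, cfg, representation)
        gen_pol, _ = assemble_generator(model, cfg, b0, representation, spaces=spaces)
        state = initial_state(model, cfg, representation, spaces=spaces)
        if tpol > 0:
            state = propagate(gen_pol, state, tpol)
        gen_det, _ = assemble_generator(model, cfg, b_zulf, representation, spaces=spaces)
        w = _observable_vector(zulf_observable(spaces.red_substrate), spaces)
        tr_vec = _trace_vector(spaces, "s")
        traj = expm_multiply(
            gen_det, state.vector, start=0.0, stop=t_acq, num=n, endpoint=True
        )
        rho_s = traj[:, : spaces.dim_s]
        tr = rho_s @ tr_vec
        total += weight * np.real((rho_s @ w) / tr)
    return Fid(
        times=times,
        signal=total,
        meta={
            "B0_T": b0,
            "tpol_s": tpol,
            "B_zulf_T": b_zulf,
            "t_acq_s": t_acq,
            "dwell_s": dwell,
            "representation": representation,
        },
    )


def spectrum(
    fid: Fid,
    apodization_rate: float | None = None,
    zero_fill: int = 2,
    mode: str = "real",
) -> Spectrum:
    """Exponentially apodized, zero-filled FFT spectrum of a real FID.

    apodization_rate (s^-1) defaults to 1/t_acq; the resulting isolated-line
    full width at half maximum is apodization_rate/pi Hz.  mode 'real'
    returns the real part after zero-order phasing; 'magnitude' the modulus.
    """
    if apodization_rate is None:
        apodization_rate = 1.0 / float(fid.times[-1])
    if apodization_rate < 0:
        raise SpinSystemError("apodization rate must be non-negative")
    if zero_fill < 1:
        raise SpinSystemError("zero-fill factor must be >= 1")
    y = fid.signal * np.exp(-apodization_rate * fid.times)
    n = len(y) * int(zero_fill)
    amp = np.fft.rfft(y, n=n)
    freq = np.fft.rfftfreq(n, d=fid.dwell)
    if mode == "real":
        out = np.real(amp)
    elif mode == "magnitude":
        out = np.abs(amp)
    else:
        raise SpinSystemError(f"unknown spectrum mode {mode!r}")
    return Spectrum(
        freq_hz=freq,
        amplitude=out,
        meta={
            **fid.meta,
            "apodization_rate_per_s": apodization_rate,
            "zero_fill": int(zero_fill),
            "mode": mode,
        },
    )
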