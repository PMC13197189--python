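# Methods

## Physical model

A spin system is a set of spin-1/2 nuclei with gyromagnetic ratios γ_l
(rad s⁻¹ T⁻¹), an isotropic J-coupling table (Hz) and longitudinal
relaxation times T1 (s). The coherent dynamics at a field B0 follows the
low-field Hamiltonian (angular-frequency units)

    H = -B0 Σ_l γ_l (1 + 10⁻⁶ δ_l) Iz_l + 2π Σ_{l<m} J_lm (I_l · I_m).

Chemical shifts δ_l (ppm) default to zero — at microtesla fields the shift
contribution is negligible for all practical purposes — but are accepted
and added to the Zeeman term. No transverse (RF) terms are supported; the
entire reduction strategy rests on [H, Fz] = 0, which RF irradiation would
break.

Relaxation uses the random-fluctuating-field (RFF) Redfield superoperator
in the extreme-narrowing limit: isotropic local field fluctuations at each
site, giving T2 = T1 per spin and a double-commutator superoperator built
from rank-1 spherical tensors. Within an equivalence group the local fields
are fully correlated and share one T1; fields at different sites are
otherwise uncorrelated. A general correlation matrix C_nl ∈ [0, 1] is
available as an opt-in (`RelaxationSpec`); the engine's default is exactly
the group-correlated form. Dipole–dipole and CSA mechanisms share the same
symmetries but are not implemented. A site with no T1 relaxes not at all
(the term is omitted rather than evaluated at T1 = ∞).

Chemical exchange is linear (fast parahydrogen supply and fast dihydrogen
exchange): dissociation at rate kd maps the complex onto the substrate by a
partial trace over the two hydrides; association at rate Wa = kd·[C]/[S]
attaches a fresh parahydrogen singlet. Density matrices are normalized to
concentration fractions (Tr ρ_S = [S]/([C]+[S])), which makes both traces
individually stationary. Nonlinear SABRE kinetics, explicit dihydrogen
species, multiple binding sites and the axial-ligand spins are out of
scope; the complex is always substrate + two hydrides.

## Symmetry reductions

*Effective spins.* A group of P magnetically equivalent protons is replaced
by one spin-K site (K from P/2 down to 0 or 1/2), with exact rational
multiplicities μ_K and weights g_K = (2K+1)μ_K/2^P computed with integer
arithmetic (`fractions.Fraction`); weights provably sum to 1. Intra-group
couplings never enter a K block; accordingly the shipped model files set
them to zero (they are accepted and simply ignored by the reduced
Hamiltonian, and have no observable effect in the unreduced one).
Per-proton observables of a group are reported as ⟨Kz⟩/P.

*ZQC restriction.* Product basis states are ordered with m descending per
site, so the total projection Fz of a basis state is the sum of per-site m
values read directly off the index. Liouville ket–bra elements carry the
coherence order q = Fz(ket) − Fz(bra); half-integer values are handled as
doubled integers so block keys are exact. The ZQC index lists q = 0 pairs
in a deterministic order (ascending Fz block, then ket then bra index), and
projection of any symmetry-respecting superoperator is an index gather —
exact, not approximate, because the ket–bra basis is orthonormal. The
hydride ordering contract (complex = substrate sites ⊗ H ⊗ H) makes the
exchange maps pure index arithmetic and is enforced by the model loader.
Within the engine, the reduced complex is therefore ordered as
[reduced substrate sites..., hydride, hydride] rather than the default
"non-equivalent first" ordering used for standalone reduced systems.

Dimension bookkeeping: full SABRE = 4^N + 4^(N+2); K-reduced = sum of
squared reduced Hilbert dimensions; ZQC = Σ_Fz dim(H_Fz)² per species,
evaluated by convolving per-site m-degeneracy profiles with exact integer
arithmetic. For N non-equivalent spins the ZQC count is the central
binomial C(2N, N) ~ 4^N/√(πN), so the reduction factor grows as √(πN).

## Numerical choices

- Row-major vectorization (|r⟩⟨c| ↦ r·d + c); the commutation superoperator
  of A is literally A⊗1 − 1⊗Aᵀ.
- All generator matrices are scipy CSR throughout; single-site operators
  are dense. Generators are assembled per constant-field segment and the
  state advanced with `scipy.sparse.linalg.expm_multiply` (action of the
  exponential, accurate to near machine precision), not a generic ODE
  stepper: the generators are stiff (exchange rates of 10–10² s⁻¹ against
  sub-hertz effective couplings) but piecewise time-independent, which is
  exactly the regime where the exponential action is cheap and exact.
- Each effective-spin configuration is solved independently and the results
  weight-averaged afterwards; results are deterministic and independent of
  execution order.
- Expectation values in the ZQC representation refuse (with
  `UnsupportedObservableError`) any observable carrying coherence-order
  components above 10⁻¹², since those are invisible after projection and
  would silently bias results.
- Field protocols are piecewise-constant; linear ramps are discretized into
  midpoint-field steps. No Magnus or commutator-free integrators.
- Spectra: the detected signal is the real expectation of the
  gamma-weighted total z magnetization of the free substrate; processing is
  exponential apodization (default rate 1/t_acq, giving an isolated-line
  FWHM of rate/π), zero-fill ×2 and a one-sided real FFT, with real-part
  and magnitude modes.
- Exchange continues during the detection stage (the experiment keeps
  bubbling parahydrogen), so an FID started from an unpolarized state is
  zero at t = 0 but grows slowly at the detection field; it is not
  identically zero.

## Shipped models and the synthetic-data caveat

The two fixtures ([¹⁵N,¹³C₂]acetonitrile, 6 spins; [¹⁵N,¹³C₄]butyronitrile,
12 spins) use *representative, synthetic* parameter sets assembled from
literature-typical values for these molecules and for Ir-IMes SABRE
complexes (e.g. ¹J_CH = 136 Hz, ¹J_CC = 57 Hz, ¹J_CN = −18 Hz, hydride
J_HH = −10 Hz, trans ²J_NH = −15 Hz, hydride T1 = 1 s, bound-substrate T1
of a few seconds). They are not measured parameters. Consequences worth
knowing:

- Everything structural — dimensions, weights, symmetry properties,
  representation equivalence — is independent of these values and exact.
- Quantitative field profiles do depend on them. With the shipped set, the
  1 s / kd = 10 s⁻¹ field scan of acetonitrile puts the ¹³C and ¹H optima
  at 0.5 µT on a 0.1 µT grid, while the ¹⁵N optimum sits at 0.3 µT; the
  true parameter set for the real complex may shift these by a grid step
  or two. Passing structural tests says nothing about agreement with any
  particular experiment.
- The `random_small` generator produces small random systems (couplings
  −20…150 Hz, T1 1–20 s, optional equivalent-proton group) used by the
  property tests; it emulates realistic coupling magnitudes but not real
  molecular topologies.

## Problem sizes and oracles

The full-space oracle propagates the 6-spin/8-spin acetonitrile model
(69 632-dimensional SABRE matrix) and is compared with the ZQC solution at
five fields, 1 s of evolution — the three representations agree to ~10⁻¹⁴
relative, far inside the 10⁻⁵ documentation threshold. Random-model
equivalence tests use 1–2 substrate spins (plus optional 2–3-proton
groups), where dense matrix exponentials are also feasible as an
independent check. Butyronitrile dynamics (≥10⁶-dimensional even reduced)
is exercised only through dimension and weight calculations; its
ZQC-SABRE maximum evaluates to 3 022 726 by the exact per-Fz sum. The
unreduced solvers refuse dimensions above a configurable cap (default 10⁶)
with an error naming the offending dimension.

## Known limitations

- Spin > 1/2 physical nuclei (quadrupolar) are not supported; effective
  spins are the only higher-spin sites.
- Strictly zero field (B0 = 0 exactly) possesses extra rotational symmetry
  that is not exploited; the ZQC machinery remains correct there but not
  maximally reduced.
- No RF pulses, no magnetometer response model, no field noise.
- Wall-clock performance depends on the sparse exponential action; the
  dominant cost is the 1-norm of the generator (set by the largest
  couplings and exchange rates) times the segment duration.
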