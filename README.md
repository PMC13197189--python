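# zulfsabre

Scalable simulation of **SABRE** (Signal Amplification By Reversible
Exchange) hyperpolarization at **zero and ultralow magnetic fields (ZULF)**.

SABRE transfers the nuclear singlet order of parahydrogen to a substrate
molecule through transient binding in an Ir complex. At microtesla fields
the polarization transfer is governed by the coherent spin dynamics of the
whole coupled network — the two parahydrogen-derived hydrides plus every
magnetic nucleus of the substrate — together with relaxation and reversible
chemical exchange. `zulfsabre` integrates the coupled master equation for
the free substrate S and the complex C in Liouville space,

```
d rho_S/dt = (L_S - Wa) rho_S + kd * Tr_H2{rho_C}
d rho_C/dt = (L_C - kd) rho_C + Wa * (rho_S ⊗ rho_pH2)
```

with `L = -i H^^ + Γ^^` (coherent evolution plus random-fluctuating-field
Redfield relaxation), `kd` the substrate dissociation rate constant and
`Wa = kd [C]/[S]` the association rate.

The package's core is two *exact* state-space reductions that make
multi-spin systems tractable:

1. **Effective spins.** A group of P magnetically equivalent protons (CH2,
   CH3) is replaced by a single spin K ∈ {P/2, …, K_min}; the physical
   result is the statistical mixture over K with exact rational weights
   g_K = (2K+1) μ_K / 2^P.
2. **Zero-quantum-coherence (ZQC) restriction.** The Hamiltonian, the RFF
   relaxation superoperator and both exchange maps conserve the coherence
   order q = Fz(ket) − Fz(bra). A density matrix that starts diagonal never
   leaves the q = 0 subspace, so every superoperator can be projected onto
   it by pure index gathering — no approximation involved.

For a 6-spin substrate (8-spin complex) this shrinks the SABRE matrix from
69 632 to 3 034 rows; for a 12-spin substrate (14-spin complex) from
2.9 × 10⁸ to about 3 × 10⁶. Unreduced full-space and K-reduced solvers are
included and used by the test suite to verify that all three
representations agree to near machine precision.

## Worked example

Two SABRE models are shipped: `acetonitrile_15N13C2` (CH3–¹³C≡¹⁵N, 6 spins)
and `butyronitrile_15N13C4` (12 spins). Their J/T1 tables are representative
synthetic parameter sets (see the YAML headers in `src/zulfsabre/data/`).

```bash
$ zulfsabre dims --model acetonitrile_15N13C2
 config weight  k_reduced  zqc
CH3=3/2    1/2      17408 3034
CH3=1/2    1/2       4352  994
full SABRE dimension:     69632
K-SABRE max dimension:    17408
ZQC SABRE max dimension:  3034
```

The two rows are the effective-spin configurations of the methyl group
(K = 3/2 and K = 1/2, equal weights); `zqc` is the size of the coupled
zero-quantum problem actually solved (substrate + complex subspaces).

```python
import zulfsabre as z

m = z.acetonitrile_15N13C2()
for b0 in (0.3e-6, 0.5e-6, 1.0e-6):          # polarization field, tesla
    pols = z.solve(m, b0, tpol=1.0)          # 1 s of parahydrogen bubbling
    print(f"B0 = {b0*1e6:.1f} uT:", {k: round(v, 5) for k, v in pols.items()})
```

prints

```
B0 = 0.3 uT: {'N1': 0.03612, 'C2': 0.00777, 'C3': 0.00606, 'CH3': 0.00314}
B0 = 0.5 uT: {'N1': 0.02747, 'C2': 0.01744, 'C3': 0.00841, 'CH3': 0.00454}
B0 = 1.0 uT: {'N1': 0.00399, 'C2': 0.00809, 'C3': 0.00153, 'CH3': 0.00074}
```

Each value is the dimensionless per-spin polarization ⟨Iz⟩ of the free
substrate (range ±1/2 for spin-1/2; multiply by 2 for percent-of-maximum),
weight-averaged over the methyl configurations. The transfer is sharply
field-dependent: the carbon and proton optima sit near 0.5 µT, and
polarization decays toward zero by a few µT.

Field scans, two-stage FID/spectrum protocols and dimension benchmarks are
available both from Python (`field_scan`, `simulate_fid`, `spectrum`,
`dimension_table`) and from the CLI (`zulfsabre fieldscan | spectrum |
bench | validate`). All CSV outputs carry a JSON sidecar with the matrix
dimensions, configuration weights and solver settings of the run.

## Layout

- `spin_system` — nuclei, J tables, equivalence groups, multiplicities and
  statistical weights, effective-spin reduction
- `operators`, `hamiltonian`, `relaxation` — spin algebra, the low-field
  Hamiltonian and its commutation superoperator, the RFF Redfield
  superoperator
- `zqc` — coherence-order labeling, ZQC indices, projections, dimension
  formulas
- `exchange` — partial trace over the hydrides and parahydrogen attachment
- `sabre_engine` — generator assembly and propagation in all three
  representations; field scans and configuration averaging
- `spectra` — ZULF observable, two-stage FIDs, Fourier-transform spectra
- `reference` — unreduced oracles and the dimension benchmark
- `io`, `cli` — YAML model files, fixtures, result serialization, CLI

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
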