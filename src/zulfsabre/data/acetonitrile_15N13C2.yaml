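# [15N,13C2]acetonitrile SABRE model (6 substrate spins, 8 in the complex).
#
# Synthetic parameter set: J couplings and T1 times are representative
# literature-style values for this isotopologue and for Ir-IMes SABRE
# hydrides (1JCH = 136 Hz, 1JCC = 57 Hz, 1JCN = -18 Hz, hydride JHH = -10 Hz,
# trans 2JNH = -15 Hz), not measurements performed here.
name: acetonitrile_15N13C2
kinetics:
  kd_per_s: 10.0
  complex_to_substrate_ratio: 0.1
substrate:
  nuclei:
    - {label: N1, isotope: 15N, t1_s: 12.0}
    - {label: C2, isotope: 13C, t1_s: 15.0}
    - {label: C3, isotope: 13C, t1_s: 15.0}
    - {label: H1, isotope: 1H}
    - {label: H2, isotope: 1H}
    - {label: H3, isotope: 1H}
  j_couplings_hz:
    - [N1, C2, -18.0]
    - [N1, C3, 3.0]
    - [C2, C3, 57.0]
    - [C3, H1, 136.0]
    - [C3, H2, 136.0]
    - [C3, H3, 136.0]
    - [C2, H1, -10.0]
    - [C2, H2, -10.0]
    - [C2, H3, -10.0]
    - [N1, H1, -1.7]
    - [N1, H2, -1.7]
    - [N1, H3, -1.7]
  groups:
    - {name: CH3, members: [H1, H2, H3], t1_s: 8.0}
complex:
  nuclei:
    - {label: N1, isotope: 15N, t1_s: 2.0}
    - {label: C2, isotope: 13C, t1_s: 3.0}
    - {label: C3, isotope: 13C, t1_s: 3.0}
    - {label: H1, isotope: 1H}
    - {label: H2, isotope: 1H}
    - {label: H3, isotope: 1H}
    - {label: HA, isotope: 1H, t1_s: 1.0}
    - {label: HB, isotope: 1H, t1_s: 1.0}
  j_couplings_hz:
    - [N1, C2, -18.0]
    - [N1, C3, 3.0]
    - [C2, C3, 57.0]
    - [C3, H1, 136.0]
    - [C3, H2, 136.0]
    - [C3, H3, 136.0]
    - [C2, H1, -10.0]
    - [C2, H2, -10.0]
    - [C2, H3, -10.0]
    - [N1, H1, -1.7]
    - [N1, H2, -1.7]
    - [N1, H3, -1.7]
    - [HA, HB, -10.0]
    - [N1, HA, -15.0]
  groups:
    - {name: CH3, members: [H1, H2, H3], t1_s: 2.0}
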