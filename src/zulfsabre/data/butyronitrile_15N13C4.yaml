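# [15N,13C4]butyronitrile SABRE model (12 substrate spins, 14 in the complex):
# N#C-CH2-CH2-CH3 with all four carbons 13C-labeled.  Two CH2 groups and one
# CH3 group of magnetically equivalent protons.
#
# Synthetic parameter set: representative literature-style J/T1 values, not
# measurements performed here.  Dynamics at this size is hours-per-field;
# the fixture is exercised for dimensions, weights and configuration
# enumeration.
name: butyronitrile_15N13C4
kinetics:
  kd_per_s: 50.0
  complex_to_substrate_ratio: 0.37
substrate:
  nuclei:
    - {label: N1, isotope: 15N, t1_s: 12.0}
    - {label: C2, isotope: 13C, t1_s: 15.0}
    - {label: C3, isotope: 13C, t1_s: 12.0}
    - {label: C4, isotope: 13C, t1_s: 10.0}
    - {label: C5, isotope: 13C, t1_s: 8.0}
    - {label: H3A, isotope: 1H}
    - {label: H3B, isotope: 1H}
    - {label: H4A, isotope: 1H}
    - {label: H4B, isotope: 1H}
    - {label: H5A, isotope: 1H}
    - {label: H5B, isotope: 1H}
    - {label: H5C, isotope: 1H}
  j_couplings_hz:
    - [N1, C2, -18.0]
    - [N1, C3, 3.0]
    - [C2, C3, 55.0]
    - [C3, C4, 34.0]
    - [C4, C5, 35.0]
    - [C3, H3A, 136.0]
    - [C3, H3B, 136.0]
    - [C4, H4A, 136.0]
    - [C4, H4B, 136.0]
    - [C5, H5A, 136.0]
    - [C5, H5B, 136.0]
    - [C5, H5C, 136.0]
    - [C2, H3A, -10.0]
    - [C2, H3B, -10.0]
    - [C3, H4A, -4.5]
    - [C3, H4B, -4.5]
    - [C4, H3A, -4.5]
    - [C4, H3B, -4.5]
    - [C4, H5A, -4.5]
    - [C4, H5B, -4.5]
    - [C4, H5C, -4.5]
    - [C5, H4A, -4.5]
    - [C5, H4B, -4.5]
    - [H3A, H4A, 7.3]
    - [H3A, H4B, 7.3]
    - [H3B, H4A, 7.3]
    - [H3B, H4B, 7.3]
    - [H4A, H5A, 7.4]
    - [H4A, H5B, 7.4]
    - [H4A, H5C, 7.4]
    - [H4B, H5A, 7.4]
    - [H4B, H5B, 7.4]
    - [H4B, H5C, 7.4]
  groups:
    - {name: CH2a, members: [H3A, H3B], t1_s: 8.0}
    - {name: CH2b, members: [H4A, H4B], t1_s: 8.0}
    - {name: CH3, members: [H5A, H5B, H5C], t1_s: 8.0}
complex:
  nuclei:
    - {label: N1, isotope: 15N, t1_s: 2.0}
    - {label: C2, isotope: 13C, t1_s: 3.0}
    - {label: C3, isotope: 13C, t1_s: 3.0}
    - {label: C4, isotope: 13C, t1_s: 3.0}
    - {label: C5, isotope: 13C, t1_s: 3.0}
    - {label: H3A, isotope: 1H}
    - {label: H3B, isotope: 1H}
    - {label: H4A, isotope: 1H}
    - {label: H4B, isotope: 1H}
    - {label: H5A, isotope: 1H}
    - {label: H5B, isotope: 1H}
    - {label: H5C, isotope: 1H}
    - {label: HA, isotope: 1H, t1_s: 1.0}
    - {label: HB, isotope: 1H, t1_s: 1.0}
  j_couplings_hz:
    - [N1, C2, -18.0]
    - [N1, C3, 3.0]
    - [C2, C3, 55.0]
    - [C3, C4, 34.0]
    - [C4, C5, 35.0]
    - [C3, H3A, 136.0]
    - [C3, H3B, 136.0]
    - [C4, H4A, 136.0]
    - [C4, H4B, 136.0]
    - [C5, H5A, 136.0]
    - [C5, H5B, 136.0]
    - [C5, H5C, 136.0]
    - [C2, H3A, -10.0]
    - [C2, H3B, -10.0]
    - [C3, H4A, -4.5]
    - [C3, H4B, -4.5]
    - [C4, H3A, -4.5]
    - [C4, H3B, -4.5]
    - [C4, H5A, -4.5]
    - [C4, H5B, -4.5]
    - [C4, H5C, -4.5]
    - [C5, H4A, -4.5]
    - [C5, H4B, -4.5]
    - [H3A, H4A, 7.3]
    - [H3A, H4B, 7.3]
    - [H3B, H4A, 7.3]
    - [H3B, H4B, 7.3]
    - [H4A, H5A, 7.4]
    - [H4A, H5B, 7.4]
    - [H4A, H5C, 7.4]
    - [H4B, H5A, 7.4]
    - [H4B, H5B, 7.4]
    - [H4B, H5C, 7.4]
    - [HA, HB, -10.0]
    - [N1, HA, -15.0]
  groups:
    - {name: CH2a, members: [H3A, H3B], t1_s: 2.0}
    - {name: CH2b, members: [H4A, H4B], t1_s: 2.0}
    - {name: CH3, members: [H5A, H5B, H5C], t1_s: 2.0}
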