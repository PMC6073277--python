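{
  "comment": "Bondi van der Waals radii (A) and standard atomic masses (Da). Radii: Bondi 1964 with the common Rowland-Taylor H value retained at 1.20. Override via config.",
  "vdw_radius": {
    "H": 1.20, "D": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39,
    "FE": 2.00, "MN": 2.00, "CU": 1.40, "SE": 1.90, "B": 1.92
  },
  "mass": {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078,
    "ZN": 65.38, "FE": 55.845, "MN": 54.938, "CU": 63.546, "SE": 78.971,
    "B": 10.81
  }
}
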