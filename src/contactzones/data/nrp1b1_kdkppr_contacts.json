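{
  "description": "Published Hirshfeld-interface composition of the NRP1-b1 / KDKPPR peptide complex (PDB 8PFE): percentage of interface area per chemical type on each side, and observed contact percentages per unordered type pair. Surface percentages are one-decimal rounded as printed. W = water oxygen (four structural waters attributed to the protein side); the peptide side carries no waters.",
  "surface_peptide": {"C": 8.8, "Hc": 42.7, "N": 5.5, "Ho/n": 22.9, "O": 20.1, "W": 0.0},
  "surface_protein": {"C": 21.4, "Hc": 30.0, "N": 1.2, "Ho/n": 15.6, "O": 15.9, "W": 16.0},
  "contacts": {
    "C|C": 1.4, "C|Hc": 21.3, "C|N": 1.3, "C|Ho/n": 3.4, "C|O": 0.4, "C|W": 1.0,
    "Hc|Hc": 10.3, "Hc|N": 3.5, "Hc|Ho/n": 7.2, "Hc|O": 15.3, "Hc|W": 4.8,
    "N|N": 0.0, "N|Ho/n": 0.5, "N|O": 0.2, "N|W": 1.3,
    "Ho/n|Ho/n": 1.6, "Ho/n|O": 17.4, "Ho/n|W": 6.9,
    "O|O": 0.3, "O|W": 2.0
  },
  "published_enrichment": {
    "C|C": 0.75, "C|Hc": 1.80, "C|N": 1.02, "C|Ho/n": 0.54, "C|O": 0.08, "C|W": 0.73,
    "Hc|Hc": 0.81, "Hc|N": 1.62, "Hc|Ho/n": 0.53, "Hc|O": 1.20, "Hc|W": 0.70,
    "N|N": 0.0, "N|Ho/n": 0.40, "N|O": 0.17, "N|W": 1.44,
    "Ho/n|Ho/n": 0.44, "Ho/n|O": 2.58, "Ho/n|W": 1.88,
    "O|O": 0.09, "O|W": 0.64
  },
  "published_grouped": {
    "surface_peptide": {"Hphob": 57.1, "Hphil": 43.0},
    "surface_protein": {"Hphob": 52.6, "Hphil": 47.4},
    "contacts": {"Hphob|Hphob": 37.8, "Hphil|Hphil": 28.2, "Hphob|Hphil": 34.0},
    "enrichment": {"Hphob|Hphob": 1.26, "Hphil|Hphil": 1.38, "Hphob|Hphil": 0.69}
  }
}
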