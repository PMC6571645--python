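"""Bundled amino-acid property scales.

``AAINDEX_SUBSET`` carries ten AAindex accessions covering hydrophobicity,
helix/sheet propensity and residue volume — the scales most informative for
discriminating anticancer from non-anticancer peptides — plus the Hopp-Woods
hydrophilicity scale.  Values are the published AAindex entries (via the
seqinr distribution of the database).  ``PSEAAC_*`` are the standard base
scales of Chou's pseudo amino acid composition: hydrophobicity,
hydrophilicity (Hopp-Woods) and side-chain mass.

Residue key order throughout the package is alphabetical by one-letter code:
ACDEFGHIKLMNPQRSTVWY.
"""

AAINDEX_SUBSET: dict[str, tuple[str, dict[str, float]]] = {
    "ARGP820101": (
        "Hydrophobicity index (Argos et al., 1982)",
        {"A": 0.61, "C": 1.07, "D": 0.46, "E": 0.47, "F": 2.02, "G": 0.07,
         "H": 0.61, "I": 2.22, "K": 1.15, "L": 1.53, "M": 1.18, "N": 0.06,
         "P": 1.95, "Q": 0.0, "R": 0.60, "S": 0.05, "T": 0.05, "V": 1.32,
         "W": 2.65, "Y": 1.88},
    ),
    "ARGP820102": (
        "Signal sequence helical potential (Argos et al., 1982)",
        {"A": 1.18, "C": 1.89, "D": 0.05, "E": 0.11, "F": 1.96, "G": 0.49,
         "H": 0.31, "I": 1.45, "K": 0.06, "L": 3.23, "M": 2.67, "N": 0.23,
         "P": 0.76, "Q": 0.72, "R": 0.20, "S": 0.97, "T": 0.84, "V": 1.08,
         "W": 0.77, "Y": 0.39},
    ),
    "ARGP820103": (
        "Membrane-buried preference parameters (Argos et al., 1982)",
        {"A": 1.56, "C": 1.23, "D": 0.14, "E": 0.23, "F": 2.03, "G": 0.62,
         "H": 0.29, "I": 1.67, "K": 0.15, "L": 2.93, "M": 2.96, "N": 0.27,
         "P": 0.76, "Q": 0.51, "R": 0.45, "S": 0.81, "T": 0.91, "V": 1.14,
         "W": 1.08, "Y": 0.68},
    ),
    "BHAR880101": (
        "Average flexibility indices (Bhaskaran-Ponnuswamy, 1988)",
        {"A": 0.357, "C": 0.346, "D": 0.511, "E": 0.497, "F": 0.314,
         "G": 0.544, "H": 0.323, "I": 0.462, "K": 0.466, "L": 0.365,
         "M": 0.295, "N": 0.463, "P": 0.509, "Q": 0.493, "R": 0.529,
         "S": 0.507, "T": 0.444, "V": 0.386, "W": 0.305, "Y": 0.420},
    ),
    "BEGF750101": (
        "Conformational parameter of inner helix (Beghin-Dirkx, 1975)",
        {"A": 1.00, "C": 0.06, "D": 0.44, "E": 0.73, "F": 0.60, "G": 0.35,
         "H": 0.60, "I": 0.73, "K": 0.60, "L": 1.00, "M": 1.00, "N": 0.35,
         "P": 0.06, "Q": 0.44, "R": 0.52, "S": 0.35, "T": 0.44, "V": 0.82,
         "W": 0.73, "Y": 0.44},
    ),
    "BEGF750102": (
        "Conformational parameter of beta-structure (Beghin-Dirkx, 1975)",
        {"A": 0.77, "C": 0.65, "D": 0.65, "E": 0.55, "F": 0.98, "G": 0.65,
         "H": 0.83, "I": 0.98, "K": 0.55, "L": 0.83, "M": 0.98, "N": 0.55,
         "P": 0.55, "Q": 0.72, "R": 0.72, "S": 0.55, "T": 0.83, "V": 0.98,
         "W": 0.77, "Y": 0.83},
    ),
    "BEGF750103": (
        "Conformational parameter of beta-turn (Beghin-Dirkx, 1975)",
        {"A": 0.37, "C": 0.84, "D": 0.97, "E": 0.53, "F": 0.53, "G": 0.97,
         "H": 0.75, "I": 0.37, "K": 0.75, "L": 0.53, "M": 0.64, "N": 0.97,
         "P": 0.97, "Q": 0.64, "R": 0.84, "S": 0.84, "T": 0.75, "V": 0.37,
         "W": 0.97, "Y": 0.84},
    ),
    "BIGC670101": (
        "Residue volume (Bigelow, 1967)",
        {"A": 52.6, "C": 68.3, "D": 68.4, "E": 84.7, "F": 113.9, "G": 36.3,
         "H": 91.9, "I": 102.0, "K": 105.1, "L": 102.0, "M": 97.7, "N": 75.7,
         "P": 73.6, "Q": 89.7, "R": 109.1, "S": 54.9, "T": 71.2, "V": 85.1,
         "W": 135.4, "Y": 116.2},
    ),
    "BIOV880102": (
        "Information value for accessibility; average fraction 23% (Biou et al., 1988)",
        {"A": 44.0, "C": 90.0, "D": -91.0, "E": -139.0, "F": 148.0, "G": -8.0,
         "H": 47.0, "I": 100.0, "K": -188.0, "L": 108.0, "M": 121.0,
         "N": -72.0, "P": -36.0, "Q": -117.0, "R": -68.0, "S": -60.0,
         "T": -54.0, "V": 117.0, "W": 163.0, "Y": 22.0},
    ),
    "ISOY800107": (
        "Normalized relative frequency of double bend (Isogai et al., 1980)",
        {"A": 1.34, "C": 1.44, "D": 1.77, "E": 2.54, "F": 0.43, "G": 0.95,
         "H": 0.00, "I": 0.52, "K": 0.79, "L": 1.05, "M": 0.00, "N": 0.92,
         "P": 0.37, "Q": 0.79, "R": 2.78, "S": 0.87, "T": 1.14, "V": 0.00,
         "W": 1.79, "Y": 0.73},
    ),
    "HOPT810101": (
        "Hydrophilicity value (Hopp-Woods, 1981)",
        {"A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
         "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
         "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
         "W": -3.4, "Y": -2.3},
    ),
}

# Standard base scales of Chou's pseudo amino acid composition.
PSEAAC_HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}

PSEAAC_HYDROPHILICITY: dict[str, float] = dict(AAINDEX_SUBSET["HOPT810101"][1])

PSEAAC_SIDECHAIN_MASS: dict[str, float] = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}
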