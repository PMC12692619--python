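"""Published per-residue propensity tables used across the package.

Each table maps the 20 standard one-letter codes to a dimensionless value.
Sources are the original scale publications as distributed by common epitope
servers; the choice of table is part of the package configuration and every
report that depends on one records which table was used.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import STANDARD_AA

#: Kyte-Doolittle hydropathy (positive = hydrophobic).  GRAVY is its mean.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Hopp-Woods hydrophilicity (positive = hydrophilic, antigenic tendency).
HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

#: Parker HPLC-derived hydrophilicity.
PARKER = {
    "A": 2.1, "R": 4.2, "N": 7.0, "D": 10.0, "C": 1.4,
    "Q": 6.0, "E": 7.8, "G": 5.7, "H": 2.1, "I": -8.0,
    "L": -9.2, "K": 5.7, "M": -4.2, "F": -9.2, "P": 2.1,
    "S": 6.5, "T": 5.2, "W": -10.0, "Y": -1.9, "V": -3.7,
}

#: Emini fractional surface probabilities; 0.37 is the random expectation,
#: so the hexapeptide product normalised by 0.37^-6 is 1.0 at random.
EMINI = {
    "A": 0.49, "R": 0.95, "N": 0.81, "D": 0.78, "C": 0.26,
    "Q": 0.84, "E": 0.84, "G": 0.48, "H": 0.66, "I": 0.34,
    "L": 0.40, "K": 0.97, "M": 0.48, "F": 0.42, "P": 0.75,
    "S": 0.65, "T": 0.70, "W": 0.51, "Y": 0.76, "V": 0.36,
}

#: Karplus-Schulz normalised B-factor flexibility; 1.0 = average mobility.
KARPLUS_SCHULZ = {
    "A": 0.984, "R": 1.008, "N": 1.048, "D": 1.068, "C": 0.906,
    "Q": 1.037, "E": 1.094, "G": 1.031, "H": 0.950, "I": 0.927,
    "L": 0.935, "K": 1.102, "M": 0.952, "F": 0.915, "P": 1.049,
    "S": 1.046, "T": 0.997, "V": 0.931, "W": 0.904, "Y": 0.929,
}

#: Chou-Fasman conformational propensities (x100; 100 = average).
CF_HELIX = {
    "A": 142, "C": 70, "D": 101, "E": 151, "F": 113,
    "G": 57, "H": 100, "I": 108, "K": 114, "L": 121,
    "M": 145, "N": 67, "P": 57, "Q": 111, "R": 98,
    "S": 77, "T": 83, "V": 106, "W": 108, "Y": 69,
}

CF_SHEET = {
    "A": 83, "C": 119, "D": 54, "E": 37, "F": 138,
    "G": 75, "H": 87, "I": 160, "K": 74, "L": 130,
    "M": 105, "N": 89, "P": 55, "Q": 110, "R": 93,
    "S": 75, "T": 119, "V": 170, "W": 137, "Y": 147,
}

CF_TURN = {
    "A": 66, "C": 119, "D": 146, "E": 74, "F": 60,
    "G": 156, "H": 95, "I": 47, "K": 101, "L": 59,
    "M": 60, "N": 156, "P": 152, "Q": 98, "R": 95,
    "S": 143, "T": 96, "V": 50, "W": 96, "Y": 114,
}

#: Chou-Fasman bend frequencies for the four positions of a beta turn.
CF_TURN_F = {
    0: {"A": 0.060, "C": 0.149, "D": 0.147, "E": 0.056, "F": 0.059,
        "G": 0.102, "H": 0.047, "I": 0.043, "K": 0.055, "L": 0.061,
        "M": 0.068, "N": 0.161, "P": 0.102, "Q": 0.074, "R": 0.070,
        "S": 0.120, "T": 0.086, "V": 0.062, "W": 0.077, "Y": 0.082},
    1: {"A": 0.076, "C": 0.053, "D": 0.110, "E": 0.060, "F": 0.041,
        "G": 0.085, "H": 0.047, "I": 0.034, "K": 0.115, "L": 0.025,
        "M": 0.082, "N": 0.083, "P": 0.301, "Q": 0.098, "R": 0.106,
        "S": 0.139, "T": 0.108, "V": 0.048, "W": 0.013, "Y": 0.065},
    2: {"A": 0.035, "C": 0.117, "D": 0.179, "E": 0.077, "F": 0.065,
        "G": 0.190, "H": 0.093, "I": 0.013, "K": 0.072, "L": 0.036,
        "M": 0.014, "N": 0.191, "P": 0.034, "Q": 0.037, "R": 0.099,
        "S": 0.125, "T": 0.065, "V": 0.028, "W": 0.064, "Y": 0.114},
    3: {"A": 0.058, "C": 0.128, "D": 0.081, "E": 0.064, "F": 0.065,
        "G": 0.152, "H": 0.054, "I": 0.056, "K": 0.095, "L": 0.070,
        "M": 0.055, "N": 0.091, "P": 0.068, "Q": 0.098, "R": 0.085,
        "S": 0.106, "T": 0.079, "V": 0.053, "W": 0.167, "Y": 0.125},
}

#: Derived random-coil propensity: the residual of the three Chou-Fasman
#: state propensities against a four-state average of 100.  Used only by the
#: derived GOR-style parameter set below.
CF_COIL = {aa: 400 - CF_HELIX[aa] - CF_SHEET[aa] - CF_TURN[aa]
           for aa in STANDARD_AA}

#: EMBOSS pKa set for Henderson-Hasselbalch net-charge / pI computation.
PKA_EMBOSS = {
    "Nterm": 8.6, "Cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}

#: Theoretical maximal accessible surface areas (A^2), Tien et al. style
#: extended Gly-X-Gly reference, for relative-accessibility normalisation.
MAX_ASA_THEORETICAL = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

#: Van der Waals radii (A) by element for solvent-accessibility calculations.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "H": 1.20, "F": 1.47,
    "CL": 1.75, "BR": 1.85, "I": 1.98,
}


@dataclass(frozen=True)
class PropensityScale:
    """A named per-residue lookup table with its windowing convention."""

    name: str
    table: dict
    default_window: int = 7
    aggregation: str = "mean"  # "mean" | "product"

    def __post_init__(self) -> None:
        missing = [aa for aa in STANDARD_AA if aa not in self.table]
        if missing:
            raise ValueError(f"scale {self.name}: missing residues {missing}")
        if self.aggregation == "mean" and (
            self.default_window < 1 or self.default_window % 2 == 0
        ):
            raise ValueError(f"scale {self.name}: window must be odd and >= 1")


# Default windows follow the scales' original publications.
SCALE_KYTE_DOOLITTLE = PropensityScale("kyte-doolittle", KYTE_DOOLITTLE, 9)
SCALE_HOPP_WOODS = PropensityScale("hopp-woods", HOPP_WOODS, 7)
SCALE_PARKER = PropensityScale("parker", PARKER, 7)
SCALE_KARPLUS_SCHULZ = PropensityScale("karplus-schulz", KARPLUS_SCHULZ, 7)
SCALE_EMINI = PropensityScale("emini", EMINI, 6, aggregation="product")

SCALES = {s.name: s for s in (
    SCALE_KYTE_DOOLITTLE, SCALE_HOPP_WOODS, SCALE_PARKER,
    SCALE_KARPLUS_SCHULZ, SCALE_EMINI,
)}
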