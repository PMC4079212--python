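"""Fixed numeric scales used by the protein descriptors.

Kept in one place so the descriptor functions are auditable against the
published scales rather than against library internals.
"""

# Kyte-Doolittle hydropathy scale (ProtParam default).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Average (not monoisotopic) residue masses in daltons, Expasy/ProtParam
# compatible.  A residue mass is the amino-acid mass minus one water.
RESIDUE_MASS_AVG = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS_AVG = 18.0153

# NCBI translation table id for the bacterial/plastid genetic code.
PLASTID_CODON_TABLE = 11
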