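"""Versioned descriptor catalogue for the 2D_3D representation.

The catalogue is an explicit manifest: the block is defined by the names
listed here, not by reflection over whatever the chemistry toolkit exposes,
so the representation is stable across toolkit releases. Fingerprints are
folded to the bit lengths declared here.
"""

from __future__ import annotations

CATALOGUE_VERSION = "1.0"

# Constitutional, topological, electrotopological and surface-area
# descriptors computed from molecular topology (rdkit.Chem.Descriptors names).
DESCRIPTORS_2D: tuple[str, ...] = (
    # constitutional
    "MolWt", "ExactMolWt", "HeavyAtomCount", "HeavyAtomMolWt",
    "NumHAcceptors", "NumHDonors", "NumHeteroatoms", "NumRotatableBonds",
    "NumValenceElectrons", "NumAromaticRings", "NumSaturatedRings",
    "NumAliphaticRings", "NumAromaticHeterocycles", "NumAromaticCarbocycles",
    "NumSaturatedHeterocycles", "NumSaturatedCarbocycles",
    "NumAliphaticHeterocycles", "NumAliphaticCarbocycles",
    "RingCount", "FractionCSP3", "NHOHCount", "NOCount",
    # graph / topological indices
    "BalabanJ", "BertzCT", "Chi0", "Chi0n", "Chi0v", "Chi1", "Chi1n",
    "Chi1v", "Chi2n", "Chi2v", "Chi3n", "Chi3v", "Chi4n", "Chi4v",
    "HallKierAlpha", "Kappa1", "Kappa2", "Kappa3", "Ipc",
    # electrotopological state
    "MaxEStateIndex", "MinEStateIndex", "MaxAbsEStateIndex",
    "MinAbsEStateIndex",
    "EState_VSA1", "EState_VSA2", "EState_VSA3", "EState_VSA4",
    "EState_VSA5", "EState_VSA6", "EState_VSA7", "EState_VSA8",
    "EState_VSA9", "EState_VSA10", "EState_VSA11",
    "VSA_EState1", "VSA_EState2", "VSA_EState3", "VSA_EState4",
    "VSA_EState5", "VSA_EState6", "VSA_EState7", "VSA_EState8",
    "VSA_EState9", "VSA_EState10",
    # charge / surface
    "MaxPartialCharge", "MinPartialCharge", "MaxAbsPartialCharge",
    "MinAbsPartialCharge",
    "TPSA", "LabuteASA", "MolLogP", "MolMR",
    "PEOE_VSA1", "PEOE_VSA2", "PEOE_VSA3", "PEOE_VSA4", "PEOE_VSA5",
    "PEOE_VSA6", "PEOE_VSA7", "PEOE_VSA8", "PEOE_VSA9", "PEOE_VSA10",
    "PEOE_VSA11", "PEOE_VSA12", "PEOE_VSA13", "PEOE_VSA14",
    "SMR_VSA1", "SMR_VSA2", "SMR_VSA3", "SMR_VSA4", "SMR_VSA5",
    "SMR_VSA6", "SMR_VSA7", "SMR_VSA8", "SMR_VSA9", "SMR_VSA10",
    "SlogP_VSA1", "SlogP_VSA2", "SlogP_VSA3", "SlogP_VSA4", "SlogP_VSA5",
    "SlogP_VSA6", "SlogP_VSA7", "SlogP_VSA8", "SlogP_VSA9", "SlogP_VSA10",
    "SlogP_VSA11", "SlogP_VSA12",
)

# Shape descriptors that require 3-D coordinates
# (rdkit.Chem.rdMolDescriptors Calc* names).
DESCRIPTORS_3D: tuple[str, ...] = (
    "CalcAsphericity", "CalcEccentricity", "CalcInertialShapeFactor",
    "CalcNPR1", "CalcNPR2", "CalcPMI1", "CalcPMI2", "CalcPMI3",
    "CalcRadiusOfGyration", "CalcSpherocityIndex", "CalcPBF",
)

# Fingerprint blocks and their folded lengths.
FINGERPRINTS: dict[str, dict] = {
    "maccs": {},                       # fixed 167 keys
    "morgan": {"radius": 2, "n_bits": 1024},
    "bcut2d": {},                      # 8 eigenvalue descriptors
}

DEFAULT_CATALOGUE: dict = {
    "version": CATALOGUE_VERSION,
    "descriptors_2d": list(DESCRIPTORS_2D),
    "descriptors_3d": list(DESCRIPTORS_3D),
    "fingerprints": dict(FINGERPRINTS),
}

# Lighter manifest used for 2-D embeddings that feed the diversity-weighted
# initialization: constitutional and graph descriptors plus MACCS and BCUT2D.
EMBEDDING_CATALOGUE: dict = {
    "version": CATALOGUE_VERSION,
    "descriptors_2d": [
        "MolWt", "HeavyAtomCount", "NumHAcceptors", "NumHDonors",
        "NumHeteroatoms", "NumRotatableBonds", "NumAromaticRings",
        "RingCount", "FractionCSP3",
        "BalabanJ", "BertzCT", "Chi0", "Chi1", "Kappa1", "Kappa2",
    ],
    "descriptors_3d": [],
    "fingerprints": {"maccs": {}, "bcut2d": {}},
}
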