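"""Residue-name tables shared by the parsers and the synthetic-file writers."""

# 20 standard amino acids, three-letter -> one-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

# A few common chemically modified residues with a well-defined standard
# parent, used when no MODRES record spells the mapping out.
MODIFIED_PARENT = {
    "MSE": "MET",  # selenomethionine
    "CSO": "CYS",  # S-hydroxycysteine
    "CME": "CYS",  # S,S-(2-hydroxyethyl)thiocysteine
    "OCS": "CYS",  # cysteine sulfonic acid
    "SEP": "SER",  # phosphoserine
    "TPO": "THR",  # phosphothreonine
    "PTR": "TYR",  # phosphotyrosine
}

# Residue names marking nucleic-acid chains in SEQRES.
NUCLEOTIDES = {"A", "C", "G", "U", "I", "N", "DA", "DC", "DG", "DT", "DI", "DU"}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def to_one_letter(resname: str, modres: dict[str, str] | None = None) -> str:
    """Map a three-letter residue name to a one-letter code.

    ``modres`` carries entry-level MODRES mappings (modified name ->
    standard parent name); modified residues inherit the parent's code,
    anything unresolvable becomes ``'X'``.
    """
    name = resname.strip().upper()
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    parent = (modres or {}).get(name) or MODIFIED_PARENT.get(name)
    if parent and parent in THREE_TO_ONE:
        return THREE_TO_ONE[parent]
    return "X"


def is_nucleic_chain(resnames: list[str]) -> bool:
    """True when every SEQRES residue name of a chain is a nucleotide."""
    return bool(resnames) and all(r.strip().upper() in NUCLEOTIDES for r in resnames)
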