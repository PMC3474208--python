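import pytest

from cysmotif import build_catalog, generate_corpus, read_pdb_entry
from cysmotif.fixtures import pdi_corpus_spec

# Minimal hand-written PDB entry: chain A APWCGHCKAL with author numbering
# 49..58 and a disulfide between author residues 52 and 55 (ordinals 4 and 7).
THIOREDOXIN_PDB = """\
HEADER    SYNTHETIC CYSTEINE FIXTURE              01-JAN-12   1TRX
COMPND    MOL_ID: 1;
SEQRES   1 A   10  ALA PRO TRP CYS GLY HIS CYS LYS ALA LEU
SSBOND   1 CYS A   52    CYS A   55                          1555   1555  2.04
HELIX    1   1 PRO A   50  HIS A   54  1                                   5
ATOM      1  CA  ALA A  49       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  PRO A  50       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  TRP A  51       0.000   0.000   0.000  1.00  0.00           C
ATOM      4  CA  CYS A  52       0.000   0.000   0.000  1.00  0.00           C
ATOM      5  CA  GLY A  53       0.000   0.000   0.000  1.00  0.00           C
ATOM      6  CA  HIS A  54       0.000   0.000   0.000  1.00  0.00           C
ATOM      7  CA  CYS A  55       0.000   0.000   0.000  1.00  0.00           C
ATOM      8  CA  LYS A  56       0.000   0.000   0.000  1.00  0.00           C
ATOM      9  CA  ALA A  57       0.000   0.000   0.000  1.00  0.00           C
ATOM     10  CA  LEU A  58       0.000   0.000   0.000  1.00  0.00           C
TER
END
"""

UNIPROT_MINIMAL = """\
ID   TEST1_SYN               Reviewed;          20 AA.
AC   P00001;
DT   01-JAN-2012, integrated into UniProtKB/Swiss-Prot.
DE   RecName: Full=Synthetic test protein;
FT   DISULFID        4..7
FT                   /note="Synthetic fixture"
FT   HELIX           2..6
FT   STRAND          8..10
FT   TURN            11..13
SQ   SEQUENCE   20 AA;  2200 MW;  0000000000000000 CRC64;
     APWCGHCKAL MCDEFGHIKL
//
"""


@pytest.fixture()
def thioredoxin_entry():
    return read_pdb_entry(THIOREDOXIN_PDB)


@pytest.fixture(scope="session")
def pdi_fixture():
    """Corpus planted with the worked-example counts: APWCGHC 12/5,
    CGHCKAL 1/1, CGHCKQL 2/0."""
    return generate_corpus(pdi_corpus_spec(seed=11))


@pytest.fixture(scope="session")
def pdi_catalog(pdi_fixture):
    entries = [read_pdb_entry(t) for t in pdi_fixture.texts.values()]
    return build_catalog(entries, k_set=(1, 2, 3, 4, 5))
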