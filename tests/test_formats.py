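"""Parsing of PDB / UniProt / FASTA text into the neutral protein model."""

import pytest

from cysmotif import (Chain, ParseWarning, SegmentKind, Source, entry_to_tsv,
                      map_author_residue, read_fasta, read_pdb_entry,
                      read_uniprot_entry)
from cysmotif.formats import (AuthorNumberingError, PdbParseError,
                              UniProtParseError)

from conftest import THIOREDOXIN_PDB, UNIPROT_MINIMAL


class TestReadPdb:
    def test_thioredoxin_chain_and_disulfide(self, thioredoxin_entry):
        e = thioredoxin_entry
        assert e.protein_id == "1TRX"
        assert e.source is Source.PDB
        assert list(e.chains) == ["A"]
        assert e.chains["A"].sequence == "APWCGHCKAL"
        assert len(e.disulfides) == 1
        d = e.disulfides[0]
        assert (d.a, d.b, d.interchain) == (("A", 4), ("A", 7), False)
        assert e.ss_segments == [e.ss_segments[0]]
        seg = e.ss_segments[0]
        assert (seg.chain_id, seg.start, seg.end, seg.kind) == ("A", 2, 6, SegmentKind.HELIX)

    def test_no_ssbond_records_yield_empty_disulfides(self):
        text = "\n".join(l for l in THIOREDOXIN_PDB.splitlines()
                         if not l.startswith("SSBOND")) + "\n"
        assert read_pdb_entry(text).disulfides == []

    def test_interchain_ssbond(self):
        text = THIOREDOXIN_PDB.replace(
            "SEQRES   1 A   10  ALA PRO TRP CYS GLY HIS CYS LYS ALA LEU",
            "SEQRES   1 A   10  ALA PRO TRP CYS GLY HIS CYS LYS ALA LEU\n"
            "SEQRES   1 B    3  GLY CYS GLY",
        ).replace(
            "SSBOND   1 CYS A   52    CYS A   55",
            "SSBOND   1 CYS A   52    CYS B    2",
        )
        entry = read_pdb_entry(text)
        assert len(entry.disulfides) == 1
        d = entry.disulfides[0]
        # chain B has no ATOM records: author number read as ordinal
        assert (d.a, d.b, d.interchain) == (("A", 4), ("B", 2), True)

    def test_missing_seqres_is_fatal(self):
        with pytest.raises(PdbParseError, match="SEQRES"):
            read_pdb_entry("HEADER    X\nEND\n")

    def test_unknown_chain_quarantined_not_dropped_silently(self):
        text = THIOREDOXIN_PDB.replace("CYS A   55", "CYS Z   55")
        with pytest.warns(ParseWarning, match="unknown chain"):
            entry = read_pdb_entry(text)
        assert entry.disulfides == []
        assert any("unknown chain" in q for q in entry.quarantined)

    def test_ssbond_to_non_cysteine_quarantined(self):
        text = THIOREDOXIN_PDB.replace("CYS A   55", "CYS A   53")
        with pytest.warns(ParseWarning, match="not cysteine"):
            entry = read_pdb_entry(text)
        assert entry.disulfides == []

    def test_malformed_fixed_column_field_reports_line_number(self):
        text = THIOREDOXIN_PDB.replace("SEQRES   1 A   10", "SEQRES   1 A   XX")
        with pytest.raises(PdbParseError, match=r"line 3"):
            read_pdb_entry(text)

    def test_engineered_mutated_flags_default_false(self, thioredoxin_entry):
        assert not thioredoxin_entry.engineered
        assert not thioredoxin_entry.mutated
        assert not thioredoxin_entry.has_nucleic_link

    def test_compnd_and_seqadv_set_flags(self):
        text = THIOREDOXIN_PDB.replace(
            "COMPND    MOL_ID: 1;",
            "COMPND    MOL_ID: 1;\nCOMPND   2 ENGINEERED: YES;\n"
            + "SEQADV 1TRX ALA A   49  UNP  P99999".ljust(49)
            + " ENGINEERED MUTATION")
        entry = read_pdb_entry(text)
        assert entry.engineered and entry.mutated

    def test_nucleic_chain_sets_flag_and_is_not_a_protein_chain(self):
        text = THIOREDOXIN_PDB.replace(
            "TER", "TER\nSEQRES   1 N    4   DA  DT  DG  DC")
        entry = read_pdb_entry(text)
        assert entry.has_nucleic_link
        assert list(entry.chains) == ["A"]

    def test_modres_maps_modified_cysteine_to_c(self):
        text = THIOREDOXIN_PDB.replace(
            "SEQRES   1 A   10  ALA PRO TRP CYS GLY HIS CYS LYS ALA LEU",
            "SEQRES   1 A   10  ALA PRO TRP CSO GLY HIS CYS LYS ALA LEU\n"
            "MODRES 1TRX CSO A   52  CYS  S-HYDROXYCYSTEINE")
        entry = read_pdb_entry(text)
        assert entry.chains["A"].sequence == "APWCGHCKAL"

    def test_unknown_residue_becomes_x(self):
        text = THIOREDOXIN_PDB.replace("ALA PRO", "ZZZ PRO")
        assert read_pdb_entry(text).chains["A"].sequence == "XPWCGHCKAL"

    def test_parse_is_deterministic(self):
        assert read_pdb_entry(THIOREDOXIN_PDB) == read_pdb_entry(THIOREDOXIN_PDB)


class TestAuthorNumbering:
    def test_offset_arithmetic(self, thioredoxin_entry):
        chain = thioredoxin_entry.chains["A"]
        assert map_author_residue(chain, 52) == 4
        assert map_author_residue(chain, 49) == 1
        assert map_author_residue(chain, 58) == 10

    def test_insertion_codes_distinguish_positions(self):
        # author numbering 10, 10A, 11 over three residues
        text = (
            "HEADER    SYNTHETIC                               01-JAN-12   1INS\n"
            "SEQRES   1 A    3  CYS GLY CYS\n"
            "ATOM      1  CA  CYS A  10       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A  10A      0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  CYS A  11       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        chain = read_pdb_entry(text).chains["A"]
        assert map_author_residue(chain, 10, " ") == 1
        assert map_author_residue(chain, 10, "A") == 2
        assert map_author_residue(chain, 11, " ") == 3

    def test_absent_author_number_raises(self, thioredoxin_entry):
        with pytest.raises(AuthorNumberingError):
            map_author_residue(thioredoxin_entry.chains["A"], 999)

    def test_fallback_without_atom_records_warns_and_uses_ordinal(self):
        chain = Chain("A", "APWCGHCKAL")
        with pytest.warns(ParseWarning, match="ordinal"):
            assert map_author_residue(chain, 4) == 4
        with pytest.warns(ParseWarning), pytest.raises(AuthorNumberingError):
            map_author_residue(chain, 999)


class TestReadUniProt:
    def test_minimal_entry(self):
        entry = read_uniprot_entry(UNIPROT_MINIMAL)
        assert entry.protein_id == "P00001"
        assert entry.source is Source.UNIPROT
        assert entry.chains["P00001"].sequence == "APWCGHCKALMCDEFGHIKL"
        assert len(entry.disulfides) == 1
        d = entry.disulfides[0]
        assert (d.a, d.b, d.interchain) == (("P00001", 4), ("P00001", 7), False)
        kinds = sorted((s.start, s.end, s.kind.value) for s in entry.ss_segments)
        assert kinds == [(2, 6, "HELIX"), (8, 10, "STRAND"), (11, 13, "TURN")]

    def test_no_disulfid_features(self):
        text = "\n".join(l for l in UNIPROT_MINIMAL.splitlines()
                         if "DISULFID" not in l and "/note" not in l) + "\n"
        assert read_uniprot_entry(text).disulfides == []

    def test_interchain_note_yields_unresolved_endpoint(self):
        text = UNIPROT_MINIMAL.replace(
            'FT   DISULFID        4..7\nFT                   /note="Synthetic fixture"',
            'FT   DISULFID        12\nFT                   /note="Interchain"')
        entry = read_uniprot_entry(text)
        assert len(entry.disulfides) == 1
        d = entry.disulfides[0]
        assert (d.a, d.b, d.interchain) == (("P00001", 12), None, True)

    def test_declared_length_mismatch_is_fatal(self):
        text = UNIPROT_MINIMAL.replace("20 AA.", "25 AA.").replace(
            "SQ   SEQUENCE   20 AA;", "SQ   SEQUENCE   25 AA;")
        with pytest.raises(UniProtParseError, match="25"):
            read_uniprot_entry(text)

    def test_out_of_range_disulfid_quarantined(self):
        text = UNIPROT_MINIMAL.replace("DISULFID        4..7", "DISULFID        4..77")
        with pytest.warns(ParseWarning, match="outside sequence"):
            entry = read_uniprot_entry(text)
        assert entry.disulfides == []


class TestReadFasta:
    def test_single_record(self):
        assert read_fasta(">q1\nAPWCGHCKAL\n") == [("q1", "APWCGHCKAL")]

    def test_multi_record_order_preserved(self):
        assert read_fasta(">a\nMK\n>b\nMR\n") == [("a", "MK"), ("b", "MR")]

    def test_lowercase_and_stop_normalised(self):
        assert read_fasta(">x\napw cgh*ckal\n") == [("x", "APWCGHCKAL")]

    def test_empty_sequence_names_the_record(self):
        with pytest.raises(ValueError, match="empty1"):
            read_fasta(">empty1\n\n>ok\nMK\n")


class TestTsvExport:
    def test_bit_exact_and_complete(self, thioredoxin_entry):
        a = entry_to_tsv(thioredoxin_entry)
        b = entry_to_tsv(read_pdb_entry(THIOREDOXIN_PDB))
        assert a == b
        assert "protein\t1TRX\tPDB\tfalse\tfalse\tfalse" in a
        assert "chain\tA\tAPWCGHCKAL" in a
        assert "disulfide\tA\t4\tA\t7\tfalse" in a
        assert "segment\tA\t2\t6\tHELIX" in a


class TestGemmiCrossCheck:
    """gemmi as an independent reader of our synthetic PDB files."""

    def test_seqres_and_ssbond_agree_with_gemmi(self, pdi_fixture):
        gemmi = pytest.importorskip("gemmi")
        for pid in list(pdi_fixture.texts)[:5]:
            truth = next(e for e in pdi_fixture.entries if e.protein_id == pid)
            st = gemmi.read_pdb_string(pdi_fixture.texts[pid])
            st.setup_entities()
            ent_seqs = {ent.name: gemmi.one_letter_code(ent.full_sequence).upper()
                        for ent in st.entities}
            masked = {(cid, pos) for cid, pos, _n, _s in truth.modres}
            for cid, seq in truth.chains.items():
                got = ent_seqs[cid]
                assert len(got) == len(seq)
                for i, (g, w) in enumerate(zip(got, seq), start=1):
                    # gemmi renders modified residues as X; we map to the parent
                    if (cid, i) not in masked:
                        assert g == w, (cid, i)
            got_bonds = set()
            for con in st.connections:
                a = (con.partner1.chain_name,
                     con.partner1.res_id.seqid.num - truth.offsets[con.partner1.chain_name] + 1)
                b = (con.partner2.chain_name,
                     con.partner2.res_id.seqid.num - truth.offsets[con.partner2.chain_name] + 1)
                got_bonds.add(frozenset((a, b)))
            want_bonds = {frozenset((bond.a, bond.b)) for bond in truth.bonds}
            assert got_bonds == want_bonds
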