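"""Readers for PDB and UniProt flat-file text and FASTA, plus the neutral
protein model they populate.

The model deliberately keeps only what the motif pipeline needs: per-chain
sequences (from SEQRES / the SQ block, never from coordinates), disulfide
annotations (SSBOND / FT DISULFID), record-based secondary structure
(HELIX / SHEET / FT HELIX,STRAND,TURN) and the provenance flags used as
query filters (engineered, mutated, nucleic-acid link).

Disulfide annotations that cannot be resolved to a cysteine in a parsed
chain are never silently dropped: they are quarantined on the entry and a
``ParseWarning`` is emitted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from typing import IO, Iterable

from Bio import SeqIO, SwissProt

from ._residues import is_nucleic_chain, to_one_letter


class ParseWarning(UserWarning):
    """Non-fatal parsing problem (quarantined annotation, fallback mapping)."""


class PdbParseError(ValueError):
    """Malformed or unusable PDB text."""


class UniProtParseError(ValueError):
    """Malformed or unusable UniProt flat-file text."""


class Source(str, Enum):
    PDB = "PDB"
    UNIPROT = "UNIPROT"


class SegmentKind(str, Enum):
    HELIX = "HELIX"
    STRAND = "STRAND"
    TURN = "TURN"


@dataclass
class Chain:
    """One polymer chain: an uppercase one-letter sequence plus, when ATOM
    records were present, the author residue numbering parallel to it."""

    chain_id: str
    sequence: str
    author_numbering: list[tuple[int, str]] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"chain {self.chain_id!r}: empty sequence")
        if not re.fullmatch(r"[A-Z\-]*", self.sequence):
            raise ValueError(f"chain {self.chain_id!r}: invalid sequence characters")
        if self.author_numbering is not None and len(self.author_numbering) != len(self.sequence):
            raise ValueError(
                f"chain {self.chain_id!r}: author numbering length "
                f"{len(self.author_numbering)} != sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class DisulfideAnnotation:
    """A disulfide bond between two sequence positions.

    ``b`` is ``None`` for UniProt "Interchain" features, whose partner lies
    outside the entry; such endpoints still count as bonded.
    """

    a: tuple[str, int]
    b: tuple[str, int] | None
    interchain: bool = False

    def __post_init__(self) -> None:
        if self.b is not None and self.a == self.b:
            raise ValueError(f"self-bonded disulfide at {self.a}")

    @property
    def endpoints(self) -> list[tuple[str, int]]:
        return [self.a] if self.b is None else [self.a, self.b]


@dataclass(frozen=True)
class SSSegment:
    """Record-based secondary-structure segment, 1-based inclusive."""

    chain_id: str
    start: int
    end: int
    kind: SegmentKind

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self}: start > end")


@dataclass
class ProteinEntry:
    protein_id: str
    source: Source
    chains: dict[str, Chain] = field(default_factory=dict)
    disulfides: list[DisulfideAnnotation] = field(default_factory=list)
    ss_segments: list[SSSegment] = field(default_factory=list)
    engineered: bool = False
    mutated: bool = False
    has_nucleic_link: bool = False
    #: annotations that referenced unknown chains / unmappable or
    #: non-cysteine positions; kept for inspection, excluded from statistics
    quarantined: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")

    def chain_sequence_digest(self) -> str:
        """Key for 100%-identity redundancy removal: the exact chain
        sequences, concatenated in chain-id order."""
        return "|".join(f"{cid}:{self.chains[cid].sequence}" for cid in sorted(self.chains))


class AuthorNumberingError(KeyError):
    """Author residue number not resolvable to a sequence ordinal."""


def map_author_residue(chain: Chain, author_num: int, icode: str = " ") -> int:
    """Map an author residue number (+ insertion code) to the 1-based
    sequence ordinal.

    Uses the ATOM-derived numbering when present; without it the author
    number is taken as the ordinal itself (with a warning), which is the
    right reading for files whose numbering starts at 1.
    """
    icode = icode or " "
    if chain.author_numbering is not None:
        try:
            return chain.author_numbering.index((author_num, icode)) + 1
        except ValueError:
            raise AuthorNumberingError(
                f"chain {chain.chain_id}: author residue {author_num}{icode.strip()} "
                "not in ATOM numbering"
            ) from None
    warnings.warn(
        f"chain {chain.chain_id}: no ATOM numbering; treating author residue "
        f"{author_num} as sequence ordinal",
        ParseWarning,
        stacklevel=2,
    )
    if 1 <= author_num <= len(chain.sequence):
        return author_num
    raise AuthorNumberingError(
        f"chain {chain.chain_id}: ordinal {author_num} outside 1..{len(chain.sequence)}"
    )


def _as_text(stream: str | IO[str]) -> str:
    return stream if isinstance(stream, str) else stream.read()


def _int_field(line: str, lo: int, hi: int, lineno: int, what: str) -> int:
    raw = line[lo:hi].strip()
    try:
        return int(raw)
    except ValueError:
        raise PdbParseError(f"line {lineno}: malformed {what} field {raw!r}") from None


def read_pdb_entry(stream: str | IO[str]) -> ProteinEntry:
    """Parse one legacy PDB-format entry into a :class:`ProteinEntry`.

    SEQRES provides the chain sequences (MODRES-aware), SSBOND the disulfide
    annotations (author numbering mapped onto SEQRES ordinals via the ATOM
    records), HELIX/SHEET the secondary structure, COMPND/SEQADV the
    engineered/mutated flags. All-nucleotide SEQRES chains only raise the
    DNA/RNA-link flag. Requires at least one SEQRES record.
    """
    text = _as_text(stream)
    protein_id = "UNKNOWN"
    seqres: dict[str, list[str]] = {}
    modres: dict[str, str] = {}
    ssbond_lines: list[tuple[int, str]] = []
    helix_lines: list[tuple[int, str]] = []
    sheet_lines: list[tuple[int, str]] = []
    atom_numbering: dict[str, list[tuple[int, str]]] = {}
    engineered = False
    mutated = False

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "HEADER":
            idcode = line[62:66].strip()
            if idcode:
                protein_id = idcode
        elif rec == "COMPND":
            if "ENGINEERED: YES" in line.upper():
                engineered = True
        elif rec == "SEQADV":
            if "MUTATION" in line[49:].upper():
                mutated = True
        elif rec == "MODRES":
            name = line[12:15].strip().upper()
            std = line[24:27].strip().upper()
            if name and std:
                modres[name] = std
        elif rec == "SEQRES":
            if len(line) < 20:
                raise PdbParseError(f"line {lineno}: truncated SEQRES record")
            chain_id = line[11].strip() or " "
            _int_field(line, 13, 17, lineno, "SEQRES numRes")
            seqres.setdefault(chain_id, []).extend(line[19:].split())
        elif rec == "SSBOND":
            ssbond_lines.append((lineno, line))
        elif rec == "HELIX ":
            helix_lines.append((lineno, line))
        elif rec == "SHEET ":
            sheet_lines.append((lineno, line))
        elif rec in ("ATOM  ", "HETATM"):
            chain_id = line[21].strip() or " "
            num = _int_field(line, 22, 26, lineno, "ATOM resSeq")
            icode = line[26:27] or " "
            nums = atom_numbering.setdefault(chain_id, [])
            if not nums or nums[-1] != (num, icode):
                nums.append((num, icode))

    if not seqres:
        raise PdbParseError("no SEQRES records: cannot establish chain sequences")

    entry = ProteinEntry(protein_id=protein_id, source=Source.PDB,
                         engineered=engineered, mutated=mutated)
    for chain_id, resnames in seqres.items():
        if is_nucleic_chain(resnames):
            entry.has_nucleic_link = True
            continue
        seq = "".join(to_one_letter(r, modres) for r in resnames)
        numbering = atom_numbering.get(chain_id)
        if numbering is not None and len(numbering) != len(seq):
            warnings.warn(
                f"{protein_id} chain {chain_id}: ATOM numbering covers "
                f"{len(numbering)} residues but SEQRES has {len(seq)}; "
                "falling back to resSeq-as-ordinal",
                ParseWarning, stacklevel=2,
            )
            numbering = None
        entry.chains[chain_id] = Chain(chain_id, seq, numbering)

    def _resolve(chain_id: str, num: int, icode: str, lineno: int, what: str,
                 require_cys: bool) -> tuple[str, int] | None:
        chain = entry.chains.get(chain_id)
        if chain is None:
            _quarantine(entry, f"line {lineno}: {what} references unknown chain {chain_id!r}")
            return None
        try:
            pos = map_author_residue(chain, num, icode)
        except AuthorNumberingError as exc:
            _quarantine(entry, f"line {lineno}: {what}: {exc}")
            return None
        if require_cys and chain.sequence[pos - 1] != "C":
            _quarantine(
                entry,
                f"line {lineno}: {what} position {pos} (author {num}) is "
                f"{chain.sequence[pos - 1]!r}, not cysteine",
            )
            return None
        return (chain_id, pos)

    for lineno, line in ssbond_lines:
        c1 = line[15].strip() or " "
        n1 = _int_field(line, 17, 21, lineno, "SSBOND seqNum1")
        i1 = line[21:22] or " "
        c2 = line[29].strip() or " "
        n2 = _int_field(line, 31, 35, lineno, "SSBOND seqNum2")
        i2 = line[35:36] or " "
        a = _resolve(c1, n1, i1, lineno, "SSBOND", require_cys=True)
        b = _resolve(c2, n2, i2, lineno, "SSBOND", require_cys=True)
        if a is None or b is None:
            continue
        if a == b:
            _quarantine(entry, f"line {lineno}: SSBOND joins a residue to itself")
            continue
        entry.disulfides.append(DisulfideAnnotation(a, b, interchain=(c1 != c2)))

    for lines, kind, c_i, s_lo, s_hi, e_i, e_lo, e_hi in (
        (helix_lines, SegmentKind.HELIX, 19, 21, 25, 31, 33, 37),
        (sheet_lines, SegmentKind.STRAND, 21, 22, 26, 32, 33, 37),
    ):
        for lineno, line in lines:
            c1 = line[c_i].strip() or " "
            c2 = line[e_i].strip() or " "
            if c1 != c2:
                _quarantine(entry, f"line {lineno}: {kind.value} segment spans chains")
                continue
            n1 = _int_field(line, s_lo, s_hi, lineno, f"{kind.value} start")
            n2 = _int_field(line, e_lo, e_hi, lineno, f"{kind.value} end")
            a = _resolve(c1, n1, " ", lineno, kind.value, require_cys=False)
            b = _resolve(c1, n2, " ", lineno, kind.value, require_cys=False)
            if a is None or b is None:
                continue
            entry.ss_segments.append(SSSegment(c1, a[1], b[1], kind))

    return entry


def _quarantine(entry: ProteinEntry, message: str) -> None:
    entry.quarantined.append(message)
    warnings.warn(f"{entry.protein_id}: {message}", ParseWarning, stacklevel=3)


def read_uniprot_entry(stream: str | IO[str]) -> ProteinEntry:
    """Parse one UniProt flat-file entry (Swiss-Prot text format).

    The entry becomes a single chain keyed by its primary accession.
    FT DISULFID features become disulfide annotations — an "Interchain"
    note yields a bonded endpoint with no partner inside the entry —
    and FT HELIX/STRAND/TURN become secondary-structure segments.
    """
    text = _as_text(stream)
    try:
        record = SwissProt.read(StringIO(text))
    except Exception as exc:  # Bio.SwissProt raises bare ValueError
        raise UniProtParseError(f"unparseable UniProt entry: {exc}") from exc
    if not record.accessions:
        raise UniProtParseError("entry has no AC line")
    acc = record.accessions[0]
    sequence = record.sequence.upper()
    if record.sequence_length != len(sequence):
        raise UniProtParseError(
            f"{acc}: SQ declares {record.sequence_length} residues "
            f"but sequence block has {len(sequence)}"
        )

    entry = ProteinEntry(protein_id=acc, source=Source.UNIPROT)
    entry.chains[acc] = Chain(acc, sequence)

    kind_map = {"HELIX": SegmentKind.HELIX, "STRAND": SegmentKind.STRAND,
                "TURN": SegmentKind.TURN}
    for feat in record.features:
        try:
            start = int(feat.location.start) + 1  # Biopython: 0-based start
            end = int(feat.location.end)
        except (TypeError, ValueError):
            _quarantine(entry, f"{feat.type} feature with non-numeric location")
            continue
        if feat.type == "DISULFID":
            note = str(feat.qualifiers.get("note", ""))
            interchain = "interchain" in note.lower()
            positions = [start] if start == end else [start, end]
            ok: list[int] = []
            for pos in positions:
                if not 1 <= pos <= len(sequence):
                    _quarantine(entry, f"DISULFID position {pos} outside sequence")
                elif sequence[pos - 1] != "C":
                    _quarantine(entry, f"DISULFID position {pos} is not cysteine")
                else:
                    ok.append(pos)
            if len(ok) != len(positions):
                continue
            if interchain:
                # partner lies in another entry; record each endpoint alone
                for pos in ok:
                    entry.disulfides.append(
                        DisulfideAnnotation((acc, pos), None, interchain=True))
            elif len(ok) == 2:
                entry.disulfides.append(
                    DisulfideAnnotation((acc, ok[0]), (acc, ok[1]), interchain=False))
            else:
                _quarantine(entry, f"intrachain DISULFID with a single position {ok[0]}")
        elif feat.type in kind_map:
            if not (1 <= start <= end <= len(sequence)):
                _quarantine(entry, f"{feat.type} segment {start}..{end} outside sequence")
                continue
            entry.ss_segments.append(SSSegment(acc, start, end, kind_map[feat.type]))
    return entry


def read_fasta(stream: str | IO[str]) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)`` pairs, in file order.

    Sequences are uppercased; ``*`` (stop) and whitespace are stripped.
    A record with an empty sequence is an error naming the record id.
    """
    handle = StringIO(stream) if isinstance(stream, str) else stream
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(handle, "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        seq = "".join(seq.split())
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        out.append((rec.id, seq))
    return out


def entry_to_tsv(entry: ProteinEntry) -> str:
    """Serialize an entry to the line-oriented TSV interchange: one tagged
    row per protein, chain, disulfide and segment. Deterministic and
    bit-exact for equal entries."""
    rows: list[str] = [
        "\t".join(["protein", entry.protein_id, entry.source.value,
                   _b(entry.engineered), _b(entry.mutated), _b(entry.has_nucleic_link)])
    ]
    for cid in sorted(entry.chains):
        rows.append("\t".join(["chain", cid, entry.chains[cid].sequence]))
    for d in sorted(entry.disulfides, key=lambda d: (d.a, d.b or ("", 0))):
        b_chain, b_pos = d.b if d.b is not None else ("", "")
        rows.append("\t".join(["disulfide", d.a[0], str(d.a[1]),
                               b_chain, str(b_pos), _b(d.interchain)]))
    for s in sorted(entry.ss_segments, key=lambda s: (s.chain_id, s.start, s.end, s.kind.value)):
        rows.append("\t".join(["segment", s.chain_id, str(s.start), str(s.end), s.kind.value]))
    return "\n".join(rows) + "\n"


def entries_to_tsv(entries: Iterable[ProteinEntry]) -> str:
    return "".join(entry_to_tsv(e) for e in entries)


def _b(flag: bool) -> str:
    return "true" if flag else "false"
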