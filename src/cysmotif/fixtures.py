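"""Synthetic PDB and UniProt flat-file corpora with exact cysteine ground
truth.

The generator emulates what the pipeline consumes from the real archives:
SEQRES/SSBOND/HELIX/SHEET/MODRES/SEQADV/COMPND records (or ID/AC/SQ/FT
lines), chains with author residue numbering offsets, intra- and
inter-chain disulfides, record-based secondary structure, and provenance
flags — with placeholder coordinates and none of the redundancy,
numbering pathologies or chemistry of real depositions.

Motif occurrences can be *planted* with exact total and bonded counts.
Random filler is drawn from the 19 non-cysteine residues, so every
cysteine in a chain is deliberate; a chain is re-drawn (deterministically)
if its filler happens to complete an unintended occurrence of a planted
motif string. Planting a motif that itself contains further cysteines
(e.g. APWCGHC) necessarily creates motif occurrences centred on those
inner cysteines, exactly as in real sequences; the inner sites are FREE
unless planted bonded themselves.

Everything is seeded; the same spec yields byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._residues import ONE_TO_THREE

_AA_NO_C = "ADEFGHIKLMNPQRSTVWY"
_SS_KINDS = ("HELIX", "STRAND", "TURN")
_SS_CODE = {"HELIX": "H", "STRAND": "E", "TURN": "T"}
_SS_RANK = {"H": 3, "E": 2, "T": 1, "C": 0}
_NUCLEOTIDES = ("DA", "DC", "DG", "DT")
_GAP = 11  # min residues between planted windows / lone cysteines


@dataclass(frozen=True)
class PlantedMotif:
    """A motif to plant with an exact occurrence count.

    ``bonded`` fixes how many of the ``count`` centre cysteines are
    disulfide-bonded; ``None`` draws each state Bernoulli(bond_probability).
    """

    motif: str
    count: int
    bonded: int | None

    def __post_init__(self) -> None:
        if len(self.motif) % 2 == 0 or not 3 <= len(self.motif) <= 11:
            raise ValueError(f"planted motif {self.motif!r}: need odd length 3..11")
        if self.motif[len(self.motif) // 2] != "C":
            raise ValueError(f"planted motif {self.motif!r}: centre must be C")
        if self.count < 1:
            raise ValueError("planted count must be >= 1")
        if self.bonded is not None and not 0 <= self.bonded <= self.count:
            raise ValueError(
                f"planted motif {self.motif!r}: bonded {self.bonded} > count {self.count}")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_proteins: int = 20
    chain_lengths: tuple[int, int] = (60, 140)
    cysteines_per_chain: tuple[int, int] = (0, 4)
    bond_probability: float = 0.5
    interchain_fraction: float = 0.1
    engineered_fraction: float = 0.1
    mutated_fraction: float = 0.1
    nucleic_fraction: float = 0.05
    planted_motifs: tuple[PlantedMotif, ...] = ()
    source: str = "pdb"  # "pdb" | "uniprot"
    two_chain_fraction: float = 0.3
    modres_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("bond_probability", "interchain_fraction", "engineered_fraction",
                     "mutated_fraction", "nucleic_fraction", "two_chain_fraction",
                     "modres_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.source not in ("pdb", "uniprot"):
            raise ValueError(f"source must be 'pdb' or 'uniprot', got {self.source!r}")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


@dataclass(frozen=True)
class TruthBond:
    a: tuple[str, int]
    b: tuple[str, int] | None  # None: partner outside the entry (interchain)
    interchain: bool


@dataclass
class TruthEntry:
    """Ground truth for one synthetic entry, independent of the parsers."""

    protein_id: str
    source: str
    chains: dict[str, str]          # chain id -> amino-acid sequence
    offsets: dict[str, int]         # chain id -> author numbering offset
    bonds: list[TruthBond] = field(default_factory=list)
    segments: list[tuple[str, int, int, str]] = field(default_factory=list)
    engineered: bool = False
    mutated: bool = False
    nucleic: bool = False
    modres: list[tuple[str, int, str, str]] = field(default_factory=list)
    nucleic_residues: list[str] = field(default_factory=list)

    def bonded_positions(self) -> dict[tuple[str, int], TruthBond]:
        out = {}
        for bond in self.bonds:
            out.setdefault(bond.a, bond)
            if bond.b is not None:
                out.setdefault(bond.b, bond)
        return out


@dataclass
class CorpusFixture:
    spec: FixtureSpec
    entries: list[TruthEntry]
    texts: dict[str, str]           # protein id -> file text
    truth: pd.DataFrame             # one row per cysteine per flank width


# ---------------------------------------------------------------------------
# independent naive oracles (kept free of the extraction module)

def naive_window(sequence: str, position: int, k: int) -> str:
    chars = []
    for off in range(-k, k + 1):
        p = position + off
        chars.append(sequence[p - 1] if 1 <= p <= len(sequence) else "-")
    return "".join(chars)


def naive_ss(segments: list[tuple[str, int, int, str]], chain_id: str,
             seq_len: int, position: int, k: int) -> str:
    codes = []
    for off in range(-k, k + 1):
        p = position + off
        if not 1 <= p <= seq_len:
            codes.append("-")
            continue
        best = "C"
        for cid, start, end, kind in segments:
            if cid == chain_id and start <= p <= end:
                code = _SS_CODE[kind]
                if _SS_RANK[code] > _SS_RANK[best]:
                    best = code
        codes.append(best)
    return "".join(codes)


# ---------------------------------------------------------------------------
# generation

def generate_corpus(spec: FixtureSpec) -> CorpusFixture:
    """Generate a corpus and its ground truth, reproducibly from the seed.

    Planted motifs appear with exactly the requested total and bonded
    counts; occurrences are distributed round-robin over the proteins.
    """
    rng = random.Random(spec.seed)
    occurrences: list[tuple[str, bool]] = []
    for pm in spec.planted_motifs:
        for i in range(pm.count):
            if pm.bonded is None:
                bonded = rng.random() < spec.bond_probability
            else:
                bonded = i < pm.bonded
            occurrences.append((pm.motif, bonded))

    per_protein: list[list[tuple[str, bool]]] = [[] for _ in range(spec.n_proteins)]
    for i, occ in enumerate(occurrences):
        per_protein[i % spec.n_proteins].append(occ)

    planted_keys = {pm.motif: len(pm.motif) // 2 for pm in spec.planted_motifs}
    entries = []
    texts = {}
    for idx in range(spec.n_proteins):
        pid = f"{1000 + idx}" if spec.source == "pdb" else f"P{10000 + idx}"
        entry = _generate_protein(rng, spec, pid, per_protein[idx], planted_keys)
        entries.append(entry)
        texts[pid] = (write_synthetic_pdb(entry) if spec.source == "pdb"
                      else write_synthetic_uniprot(entry))
    return CorpusFixture(spec, entries, texts, truth_table(entries))


def _generate_protein(rng: random.Random, spec: FixtureSpec, pid: str,
                      plants: list[tuple[str, bool]],
                      planted_keys: dict[str, int]) -> TruthEntry:
    for _attempt in range(100):
        entry = _attempt_protein(rng, spec, pid, plants)
        if _plant_check(entry, plants, planted_keys):
            return entry
    raise RuntimeError(f"{pid}: could not realise planted motifs without collisions")


def _attempt_protein(rng: random.Random, spec: FixtureSpec, pid: str,
                     plants: list[tuple[str, bool]]) -> TruthEntry:
    if spec.source == "pdb":
        n_chains = 2 if rng.random() < spec.two_chain_fraction else 1
        chain_ids = ["A", "B"][:n_chains]
    else:
        chain_ids = [pid]

    # lay out each chain as blocks separated by cysteine-free filler gaps
    blocks: dict[str, list[tuple]] = {cid: [] for cid in chain_ids}
    for occ_id, (motif, bonded) in enumerate(plants):
        cid = rng.choice(chain_ids)
        blocks[cid].append(("motif", occ_id, motif))
        if bonded:
            blocks[cid].append(("plant_partner", occ_id))
    free_cys: list[tuple[str, int]] = []
    bonded_cys: list[tuple[str, int]] = []
    for cid in chain_ids:
        for _ in range(rng.randint(*spec.cysteines_per_chain)):
            blocks[cid].append(("cys", rng.random() < spec.bond_probability))

    chains: dict[str, str] = {}
    plant_center: dict[int, tuple[str, int]] = {}
    plant_partner: dict[int, tuple[str, int]] = {}
    for cid in chain_ids:
        rng.shuffle(blocks[cid])
        seq: list[str] = []
        for block in blocks[cid]:
            seq.extend(rng.choice(_AA_NO_C) for _ in range(rng.randint(_GAP, 2 * _GAP)))
            if block[0] == "motif":
                _, occ_id, motif = block
                k = len(motif) // 2
                plant_center[occ_id] = (cid, len(seq) + k + 1)
                seq.extend(motif)
            elif block[0] == "plant_partner":
                plant_partner[block[1]] = (cid, len(seq) + 1)
                seq.append("C")
            else:
                pos = (cid, len(seq) + 1)
                (bonded_cys if block[1] else free_cys).append(pos)
                seq.append("C")
        seq.extend(rng.choice(_AA_NO_C) for _ in range(rng.randint(_GAP, 2 * _GAP)))
        target = rng.randint(*spec.chain_lengths)
        while len(seq) < target:
            seq.append(rng.choice(_AA_NO_C))
        chains[cid] = "".join(seq)

    entry = TruthEntry(protein_id=pid, source=spec.source, chains=chains,
                       offsets={}, bonds=[])

    for occ_id, (motif, bonded) in enumerate(plants):
        if bonded:
            entry.bonds.append(TruthBond(plant_center[occ_id],
                                         plant_partner[occ_id], interchain=False))
    _pair_random_cysteines(rng, spec, entry, bonded_cys, chain_ids)

    # chain decorations; legacy PDB text has no TURN record, so turns are
    # generated only for UniProt entries
    kinds = _SS_KINDS if spec.source == "uniprot" else ("HELIX", "STRAND")
    for cid in chain_ids:
        entry.offsets[cid] = 1 if rng.random() < 0.4 else rng.randint(2, 500)
        length = len(chains[cid])
        for _ in range(rng.randint(0, 3)):
            start = rng.randint(1, length)
            end = min(length, start + rng.randint(2, 12))
            entry.segments.append((cid, start, end, rng.choice(kinds)))

    if spec.source == "pdb":
        entry.engineered = rng.random() < spec.engineered_fraction
        entry.mutated = rng.random() < spec.mutated_fraction
        entry.nucleic = rng.random() < spec.nucleic_fraction
        if entry.nucleic:
            entry.nucleic_residues = [rng.choice(_NUCLEOTIDES)
                                      for _ in range(rng.randint(8, 20))]
        if rng.random() < spec.modres_fraction:
            # a modified cysteine (parent CYS): sequence letter stays 'C'
            cands = [(cid, p) for cid, s in chains.items()
                     for p in range(1, len(s) + 1) if s[p - 1] == "C"]
            if cands:
                cid, p = rng.choice(cands)
                entry.modres.append((cid, p, "CSO", "CYS"))
        if rng.random() < spec.modres_fraction:
            # selenomethionine somewhere in the filler
            cands = [(cid, p) for cid, s in chains.items()
                     for p in range(1, len(s) + 1) if s[p - 1] == "M"]
            if cands:
                cid, p = rng.choice(cands)
                entry.modres.append((cid, p, "MSE", "MET"))
    return entry


def _pair_random_cysteines(rng: random.Random, spec: FixtureSpec,
                           entry: TruthEntry, bonded_cys: list[tuple[str, int]],
                           chain_ids: list[str]) -> None:
    """Pair the randomly placed bonded cysteines into disulfides; an odd
    leftover stays FREE. UniProt entries mark some bonded sites as
    partner-unresolved interchain bonds instead."""
    pool = list(bonded_cys)
    rng.shuffle(pool)
    if spec.source == "uniprot":
        kept = []
        for site in pool:
            if rng.random() < spec.interchain_fraction:
                entry.bonds.append(TruthBond(site, None, interchain=True))
            else:
                kept.append(site)
        pool = kept
    by_chain: dict[str, list[tuple[str, int]]] = {cid: [] for cid in chain_ids}
    for site in pool:
        by_chain[site[0]].append(site)
    while sum(len(v) for v in by_chain.values()) >= 2:
        nonempty = [cid for cid in chain_ids if by_chain[cid]]
        cross_possible = len(nonempty) >= 2
        if cross_possible and rng.random() < spec.interchain_fraction:
            c1, c2 = nonempty[0], nonempty[1]
        else:
            c1 = max(nonempty, key=lambda cid: len(by_chain[cid]))
            if len(by_chain[c1]) >= 2:
                c2 = c1
            elif cross_possible:
                c2 = next(cid for cid in nonempty if cid != c1)
            else:
                break  # a single site left on the only populated chain
        a = by_chain[c1].pop()
        b = by_chain[c2].pop()
        entry.bonds.append(TruthBond(a, b, interchain=(c1 != c2)))
    # any leftover site stays FREE (not appended to bonds)


def _plant_check(entry: TruthEntry, plants: list[tuple[str, bool]],
                 planted_keys: dict[str, int]) -> bool:
    """True when every planted motif occurs exactly at its planted centres
    and nowhere else in the entry."""
    if not planted_keys:
        return True
    expected: dict[str, int] = {}
    for motif, _ in plants:
        expected[motif] = expected.get(motif, 0) + 1
    found: dict[str, int] = {m: 0 for m in planted_keys}
    for cid, seq in entry.chains.items():
        for pos in (i + 1 for i, aa in enumerate(seq) if aa == "C"):
            for motif, k in planted_keys.items():
                if naive_window(seq, pos, k) == motif:
                    found[motif] += 1
    return all(found[m] == expected.get(m, 0) for m in planted_keys)


# ---------------------------------------------------------------------------
# ground truth table

def truth_table(entries: list[TruthEntry],
                k_set: tuple[int, ...] = (1, 2, 3, 4, 5)) -> pd.DataFrame:
    """One row per cysteine per flank width, computed with the naive
    oracles: the reference the pipeline output is compared against."""
    rows = []
    for entry in entries:
        bonded = entry.bonded_positions()
        for cid in entry.chains:
            seq = entry.chains[cid]
            for pos in (i + 1 for i, aa in enumerate(seq) if aa == "C"):
                bond = bonded.get((cid, pos))
                if bond is None:
                    state, partner, scope = "FREE", "", ""
                elif bond.b is None:
                    state, partner, scope = "BONDED", "", "INTERCHAIN"
                else:
                    other = bond.b if bond.a == (cid, pos) else bond.a
                    state = "BONDED"
                    partner = f"{other[0]}:{other[1]}"
                    scope = "INTERCHAIN" if bond.interchain else "INTRACHAIN"
                for k in k_set:
                    rows.append({
                        "protein_id": entry.protein_id, "chain_id": cid,
                        "position": pos, "k": k,
                        "motif": naive_window(seq, pos, k),
                        "ss": naive_ss(entry.segments, cid, len(seq), pos, k),
                        "state": state, "scope": scope, "partner": partner,
                        "engineered": entry.engineered, "mutated": entry.mutated,
                        "has_nucleic_link": entry.nucleic,
                    })
    columns = ["protein_id", "chain_id", "position", "k", "motif", "ss",
               "state", "scope", "partner", "engineered", "mutated",
               "has_nucleic_link"]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# writers

def _fixed(*fields: tuple[int, str], width: int = 80) -> str:
    """Build a fixed-column record line; columns are 1-based."""
    buf = [" "] * width
    for col, text in fields:
        for i, ch in enumerate(text):
            buf[col - 1 + i] = ch
    return "".join(buf).rstrip()


def _res3(entry: TruthEntry, cid: str, pos: int, aa: str) -> str:
    for mcid, mpos, name, _std in entry.modres:
        if (mcid, mpos) == (cid, pos):
            return name
    return ONE_TO_THREE[aa]


def write_synthetic_pdb(entry: TruthEntry) -> str:
    """Emit legacy PDB text that the parser maps back to exactly this truth."""
    for bond in entry.bonds:
        for end in (bond.a, bond.b):
            if end is not None and entry.chains[end[0]][end[1] - 1] != "C":
                raise ValueError(f"{entry.protein_id}: bond endpoint {end} is not C")
    for cid, start, end, _kind in entry.segments:
        if not 1 <= start <= end <= len(entry.chains[cid]):
            raise ValueError(f"{entry.protein_id}: segment outside chain {cid}")

    lines = [_fixed((1, "HEADER"), (11, "SYNTHETIC CYSTEINE FIXTURE"),
                    (51, "01-JAN-12"), (63, entry.protein_id[:4]))]
    lines.append(_fixed((1, "COMPND"), (11, "MOL_ID: 1;")))
    if entry.engineered:
        lines.append(_fixed((1, "COMPND"), (9, "2"), (11, "ENGINEERED: YES;")))
    if entry.mutated:
        cid0 = next(iter(entry.chains))
        lines.append(_fixed((1, "SEQADV"), (8, entry.protein_id[:4]), (13, "ALA"),
                            (17, cid0), (19, f"{entry.offsets[cid0]:>4}"),
                            (25, "UNP  P99999    GLY"), (50, "ENGINEERED MUTATION")))
    chain_order = list(entry.chains)
    nucleic_id = None
    if entry.nucleic:
        nucleic_id = next(c for c in "NXYZ" if c not in entry.chains)
    for cid in chain_order:
        seq = entry.chains[cid]
        names = [_res3(entry, cid, i + 1, aa) for i, aa in enumerate(seq)]
        lines.extend(_seqres_lines(cid, names))
    if nucleic_id:
        lines.extend(_seqres_lines(nucleic_id, entry.nucleic_residues))
    for cid, pos, name, std in entry.modres:
        lines.append(_fixed((1, "MODRES"), (8, entry.protein_id[:4]), (13, name),
                            (17, cid), (19, f"{entry.offsets[cid] + pos - 1:>4}"),
                            (25, std), (30, "SYNTHETIC MODIFIED RESIDUE")))
    helix_n = sheet_n = 0
    for cid, start, end, kind in entry.segments:
        off = entry.offsets[cid]
        a3 = ONE_TO_THREE.get(entry.chains[cid][start - 1], "UNK")
        b3 = ONE_TO_THREE.get(entry.chains[cid][end - 1], "UNK")
        if kind == "HELIX":
            helix_n += 1
            lines.append(_fixed((1, "HELIX"), (8, f"{helix_n:>3}"), (12, f"{helix_n:>3}"),
                                (16, a3), (20, cid), (22, f"{off + start - 1:>4}"),
                                (27, b3), (32, cid), (34, f"{off + end - 1:>4}"),
                                (39, "1"), (72, f"{end - start + 1:>5}")))
        elif kind == "STRAND":
            sheet_n += 1
            lines.append(_fixed((1, "SHEET"), (8, f"{sheet_n:>3}"), (12, f"S{sheet_n:>2}"),
                                (15, " 1"), (18, a3), (22, cid),
                                (23, f"{off + start - 1:>4}"), (29, b3), (33, cid),
                                (34, f"{off + end - 1:>4}"), (39, "0")))
        # TURN has no legacy PDB record; turns occur only in UniProt fixtures
    ser = 0
    for bond in entry.bonds:
        ser += 1
        (c1, p1), (c2, p2) = bond.a, bond.b
        lines.append(_fixed((1, "SSBOND"), (8, f"{ser:>3}"), (12, "CYS"), (16, c1),
                            (18, f"{entry.offsets[c1] + p1 - 1:>4}"),
                            (26, "CYS"), (30, c2),
                            (32, f"{entry.offsets[c2] + p2 - 1:>4}"),
                            (60, "1555   1555"), (74, "2.04")))
    serial = 0
    for cid in chain_order:
        seq = entry.chains[cid]
        off = entry.offsets[cid]
        for i, aa in enumerate(seq):
            serial += 1
            lines.append(_fixed((1, "ATOM"), (7, f"{serial:>5}"), (14, "CA"),
                                (18, _res3(entry, cid, i + 1, aa)), (22, cid),
                                (23, f"{off + i:>4}"),
                                (31, "   0.000   0.000   0.000  1.00  0.00"),
                                (78, "C")))
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _seqres_lines(cid: str, names: list[str]) -> list[str]:
    lines = []
    for i in range(0, len(names), 13):
        chunk = names[i:i + 13]
        body = " ".join(f"{n:>3}" for n in chunk)
        lines.append(_fixed((1, "SEQRES"), (8, f"{i // 13 + 1:>3}"), (12, cid),
                            (14, f"{len(names):>4}"), (20, body)))
    return lines


def write_synthetic_uniprot(entry: TruthEntry) -> str:
    """Emit a Swiss-Prot flat-file entry matching this truth exactly."""
    (cid,) = entry.chains
    seq = entry.chains[cid]
    for bond in entry.bonds:
        for end in (bond.a, bond.b):
            if end is not None and seq[end[1] - 1] != "C":
                raise ValueError(f"{entry.protein_id}: bond endpoint {end} is not C")
    acc = entry.protein_id
    lines = [
        f"ID   {f'{acc}_SYN':<24}Reviewed;{len(seq):>12} AA.",
        f"AC   {acc};",
        "DT   01-JAN-2012, integrated into UniProtKB/Swiss-Prot.",
        "DE   RecName: Full=Synthetic cysteine-motif fixture;",
    ]
    for bond in entry.bonds:
        if bond.b is None:
            lines.append(f"FT   DISULFID        {bond.a[1]}")
            lines.append('FT                   /note="Interchain"')
        else:
            lo, hi = sorted((bond.a[1], bond.b[1]))
            lines.append(f"FT   DISULFID        {lo}..{hi}")
            lines.append('FT                   /note="Synthetic fixture"')
    for _cid, start, end, kind in entry.segments:
        lines.append(f"FT   {kind:<16}{start}..{end}")
    lines.append(f"SQ   SEQUENCE   {len(seq)} AA;  {len(seq) * 110} MW;"
                 "  0000000000000000 CRC64;")
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60]
        grouped = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"     {grouped}")
    lines.append("//")
    return "\n".join(lines) + "\n"


def write_corpus(fixture: CorpusFixture, directory: str | Path) -> Path:
    """Write the corpus as a local mirror tree: one file per entry under
    pdb/ or uniprot/, plus the ground-truth table as truth.tsv."""
    directory = Path(directory)
    sub = directory / fixture.spec.source
    sub.mkdir(parents=True, exist_ok=True)
    ext = ".pdb" if fixture.spec.source == "pdb" else ".txt"
    for pid, text in fixture.texts.items():
        (sub / f"{pid}{ext}").write_text(text)
    fixture.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    return directory


# ---------------------------------------------------------------------------
# worked-example helpers

#: Table-2-style study conditions: the thioredoxin-motif contexts of protein
#: disulphide isomerase with their corpus occurrence counts (APWCGHC mixed
#: 5/12, CGHCKAL always bonded 1/1, CGHCKQL always nonbonded 0/2).
PDI_PLANTS = (PlantedMotif("APWCGHC", 12, 5),
              PlantedMotif("CGHCKAL", 1, 1),
              PlantedMotif("CGHCKQL", 2, 0))


def pdi_corpus_spec(seed: int) -> FixtureSpec:
    """Fixture spec whose built catalog carries the worked-example counts."""
    return FixtureSpec(seed=seed, n_proteins=15, chain_lengths=(80, 160),
                       cysteines_per_chain=(0, 3), bond_probability=0.4,
                       planted_motifs=PDI_PLANTS, source="pdb")


def synthetic_pdi_sequence(seed: int = 0, length: int = 480) -> str:
    """A synthetic stand-in for the PDI query sequence: cysteine-free
    filler carrying the first thioredoxin context APWCGHCKAL at positions
    49–58 (active-site cysteines 52 and 55) and the second context
    APWCGHCKQL at 393–402 (cysteines 396 and 399), plus two lone free
    cysteines. Not the real P07237 sequence."""
    if length < 410:
        raise ValueError("length must be >= 410 to hold both contexts")
    rng = random.Random(seed)
    seq = [rng.choice(_AA_NO_C) for _ in range(length)]
    for start, context in ((49, "APWCGHCKAL"), (393, "APWCGHCKQL")):
        seq[start - 1:start - 1 + len(context)] = context
    seq[149] = "C"
    seq[299] = "C"
    return "".join(seq)
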