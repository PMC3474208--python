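"""Cysteine identification, flanking-motif windowing and bonding-state
assignment.

A motif is the cysteine plus ``k`` flanking residues on each side
(``k`` in 1..5), always 2k+1 characters with the cysteine at the centre;
positions past a chain terminus are padded with ``'-'`` so that every
cysteine yields exactly one motif at every width. A cysteine is BONDED
iff it appears in at least one disulfide annotation; cysteines
coordinated to metals or otherwise unannotated are FREE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

from .formats import ParseWarning, ProteinEntry, SegmentKind

FLANK_WIDTHS = (1, 2, 3, 4, 5)

#: precedence when record-based segments overlap
_SS_CODE = {SegmentKind.HELIX: "H", SegmentKind.STRAND: "E", SegmentKind.TURN: "T"}
_SS_RANK = {"H": 3, "E": 2, "T": 1, "C": 0}


class BondState(str, Enum):
    BONDED = "BONDED"
    FREE = "FREE"


class BondScope(str, Enum):
    INTRACHAIN = "INTRACHAIN"
    INTERCHAIN = "INTERCHAIN"


@dataclass(frozen=True)
class CysteineSite:
    protein_id: str
    chain_id: str
    position: int  # 1-based
    state: BondState
    partner: tuple[str, int] | None = None
    scope: BondScope | None = None


@dataclass(frozen=True)
class MotifRecord:
    motif: str
    k: int
    site: CysteineSite
    ss: str

    def __post_init__(self) -> None:
        if len(self.motif) != 2 * self.k + 1 or self.motif[self.k] != "C":
            raise ValueError(f"motif {self.motif!r} is not centred on C at width {self.k}")
        if len(self.ss) != len(self.motif):
            raise ValueError("secondary-structure string length mismatch")


def find_cysteines(sequence: str) -> list[int]:
    """Ascending 1-based positions of every 'C' in an uppercase sequence."""
    return [i + 1 for i, aa in enumerate(sequence) if aa == "C"]


def extract_motif(sequence: str, position: int, k: int) -> str:
    """The 2k+1 window centred on the cysteine at ``position`` (1-based),
    '-'-padded where the window runs past a terminus."""
    if k not in FLANK_WIDTHS:
        raise ValueError(f"flank width must be in {FLANK_WIDTHS}, got {k}")
    if not 1 <= position <= len(sequence) or sequence[position - 1] != "C":
        raise ValueError(f"position {position} is not a cysteine in this sequence")
    i = position - 1
    left = sequence[max(0, i - k):i].rjust(k, "-")
    right = sequence[i + 1:i + 1 + k].ljust(k, "-")
    return left + "C" + right


def assign_bonding_states(entry: ProteinEntry) -> list[CysteineSite]:
    """One :class:`CysteineSite` per cysteine per chain, in (chain, position)
    order, bonded iff covered by a disulfide annotation.

    A cysteine listed in several annotations is BONDED once; its partner is
    the first resolvable one. Scope is INTRA-/INTERCHAIN when the partner
    chain is known, and INTERCHAIN for partner-unresolved annotations that
    explicitly declare an interchain bond.
    """
    bonded: dict[tuple[str, int], tuple[tuple[str, int] | None, BondScope | None]] = {}
    for ann in entry.disulfides:
        for idx, end in enumerate(ann.endpoints):
            chain = entry.chains.get(end[0])
            if chain is None or chain.sequence[end[1] - 1] != "C":
                warnings.warn(
                    f"{entry.protein_id}: disulfide endpoint {end} is not a "
                    "cysteine; excluded",
                    ParseWarning, stacklevel=2)
                continue
            if end in bonded:
                continue
            if ann.b is None:
                partner = None
                scope = BondScope.INTERCHAIN if ann.interchain else None
            else:
                partner = ann.endpoints[1 - idx]
                scope = (BondScope.INTERCHAIN if ann.interchain
                         else BondScope.INTRACHAIN)
            bonded[end] = (partner, scope)

    sites: list[CysteineSite] = []
    for chain_id, chain in entry.chains.items():
        for pos in find_cysteines(chain.sequence):
            key = (chain_id, pos)
            if key in bonded:
                partner, scope = bonded[key]
                sites.append(CysteineSite(entry.protein_id, chain_id, pos,
                                          BondState.BONDED, partner, scope))
            else:
                sites.append(CysteineSite(entry.protein_id, chain_id, pos,
                                          BondState.FREE))
    return sites


def annotate_secondary_structure(entry: ProteinEntry, chain_id: str,
                                 position: int, k: int) -> str:
    """Per-residue code over the motif window: H (helix), E (strand),
    T (turn), C (coil default), '-' at padded positions; overlaps resolved
    by precedence H > E > T."""
    chain = entry.chains[chain_id]
    length = len(chain.sequence)
    codes = []
    for offset in range(-k, k + 1):
        pos = position + offset
        if not 1 <= pos <= length:
            codes.append("-")
            continue
        best = "C"
        for seg in entry.ss_segments:
            if seg.chain_id == chain_id and seg.start <= pos <= seg.end:
                code = _SS_CODE[seg.kind]
                if _SS_RANK[code] > _SS_RANK[best]:
                    best = code
        codes.append(best)
    return "".join(codes)


def extract_all(entry: ProteinEntry, k: int) -> list[MotifRecord]:
    """Every motif record of an entry at one flank width: one record per
    cysteine per chain, ordered by (chain, position)."""
    records = []
    for chain_id, site_list in _sites_by_chain(entry).items():
        chain = entry.chains[chain_id]
        for site in site_list:
            records.append(MotifRecord(
                motif=extract_motif(chain.sequence, site.position, k),
                k=k,
                site=site,
                ss=annotate_secondary_structure(entry, chain_id, site.position, k),
            ))
    return records


def _sites_by_chain(entry: ProteinEntry) -> dict[str, list[CysteineSite]]:
    grouped: dict[str, list[CysteineSite]] = {cid: [] for cid in entry.chains}
    for site in assign_bonding_states(entry):
        grouped[site.chain_id].append(site)
    return grouped
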