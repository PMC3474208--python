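"""Motif catalogs: aggregation of motif records into per-unique-motif
bonding statistics, bonding-behaviour classes, 100%-identity redundancy
removal, positional amino-acid propensities, incremental update and TSV
persistence.

The central statistic is the *bond coefficient* of a unique (motif, k):
bonded occurrences / total occurrences across the corpus, in [0, 1].
Coefficient 1 marks motifs that are always bonded, 0 always nonbonded,
anything in between mixed behaviour. Each cysteine occurrence (per chain,
per protein, per dataset) contributes exactly one count.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._residues import AMINO_ACIDS
from .extraction import (BondScope, BondState, CysteineSite, MotifRecord,
                         extract_all)
from .formats import ParseWarning, ProteinEntry, Source

logger = logging.getLogger("cysmotif.catalog")


class Dataset(str, Enum):
    ALL = "ALL"
    NONREDUNDANT = "NONREDUNDANT"


class MotifClass(str, Enum):
    ALWAYS_BONDED = "ALWAYS_BONDED"
    ALWAYS_NONBONDED = "ALWAYS_NONBONDED"
    MIXED = "MIXED"


def coefficient(total: int, bonded: int) -> float:
    """Bond coefficient: bonded / total occurrences of a unique motif."""
    if total <= 0:
        raise ValueError("coefficient undefined for total == 0")
    if not 0 <= bonded <= total:
        raise ValueError(f"bonded count {bonded} outside 0..{total}")
    return bonded / total


def render_coefficient(value: float) -> str:
    """Report rendering: three decimals, round-half-even (5/12 -> '0.417')."""
    return str(Decimal(repr(value)).quantize(Decimal("0.001"), ROUND_HALF_EVEN))


@dataclass
class MotifStats:
    motif: str
    k: int
    total: int
    bonded: int

    def __post_init__(self) -> None:
        if self.total < 1 or not 0 <= self.bonded <= self.total:
            raise ValueError(f"invalid counts total={self.total} bonded={self.bonded}")

    @property
    def coefficient(self) -> float:
        return coefficient(self.total, self.bonded)

    @property
    def cls(self) -> MotifClass:
        return classify_motif(self)


def classify_motif(stats: MotifStats) -> MotifClass:
    """Bonding-behaviour class of a unique motif: always bonded
    (coefficient 1), always nonbonded (0), or mixed."""
    if stats.bonded == stats.total:
        return MotifClass.ALWAYS_BONDED
    if stats.bonded == 0:
        return MotifClass.ALWAYS_NONBONDED
    return MotifClass.MIXED


@dataclass(frozen=True)
class ProteinInfo:
    """Per-protein row kept alongside the records: the query filters operate
    on these flags."""

    protein_id: str
    source: Source
    engineered: bool
    mutated: bool
    has_nucleic_link: bool
    seq_digest: str


@dataclass
class MotifCatalog:
    dataset: Dataset
    source: Source
    k_set: tuple[int, ...]
    records: list[MotifRecord] = field(default_factory=list)
    stats: dict[tuple[str, int], MotifStats] = field(default_factory=dict)
    proteins: dict[str, ProteinInfo] = field(default_factory=dict)

    def rebuild_stats(self) -> dict[tuple[str, int], MotifStats]:
        """Recompute the stats map from the records (the stored map must be
        a fixed point of this)."""
        return aggregate_stats(self.records)

    def lookup(self, motif: str, k: int) -> MotifStats | None:
        return self.stats.get((motif, k))


def aggregate_stats(records: Iterable[MotifRecord]) -> dict[tuple[str, int], MotifStats]:
    counts: dict[tuple[str, int], list[int]] = {}
    for rec in records:
        c = counts.setdefault((rec.motif, rec.k), [0, 0])
        c[0] += 1
        if rec.site.state is BondState.BONDED:
            c[1] += 1
    return {key: MotifStats(key[0], key[1], t, b)
            for key, (t, b) in sorted(counts.items())}


def deduplicate_proteins(entries: Sequence[ProteinEntry]) -> list[ProteinEntry]:
    """100%-identity redundancy removal: group entries by exact concatenated
    chain-sequence content and keep the lexicographically smallest protein
    id of each group. Output preserves the input order of survivors."""
    best: dict[str, str] = {}
    for e in entries:
        digest = e.chain_sequence_digest()
        if digest not in best or e.protein_id < best[digest]:
            best[digest] = e.protein_id
    keep = set(best.values())
    seen: set[str] = set()
    out = []
    for e in entries:
        if e.protein_id in keep and e.protein_id not in seen:
            out.append(e)
            seen.add(e.protein_id)
    return out


def build_catalog(entries: Sequence[ProteinEntry],
                  k_set: Iterable[int] = (1, 2, 3, 4, 5),
                  dataset: Dataset = Dataset.ALL,
                  source: Source | None = None) -> MotifCatalog:
    """Build a catalog from parsed entries: motif records for every cysteine
    at every width in ``k_set``, plus the per-unique-motif statistics.

    Duplicate protein ids: last entry wins, with a warning. With
    ``dataset=NONREDUNDANT`` the 100%-identity filter is applied first.
    """
    k_set = tuple(sorted(set(k_set)))
    if any(k not in (1, 2, 3, 4, 5) for k in k_set):
        raise ValueError(f"flank widths must lie in 1..5, got {k_set}")

    unique: dict[str, ProteinEntry] = {}
    for e in entries:
        if e.protein_id in unique:
            warnings.warn(f"duplicate protein id {e.protein_id}: keeping the last entry",
                          ParseWarning, stacklevel=2)
        unique[e.protein_id] = e
    pool = list(unique.values())

    sources = {e.source for e in pool}
    if source is None:
        if len(sources) > 1:
            raise ValueError("entries mix PDB and UniProt; build one catalog per source")
        source = next(iter(sources), Source.PDB)
    elif sources - {source}:
        raise ValueError(f"entries do not all have source {source.value}")

    if dataset is Dataset.NONREDUNDANT:
        pool = deduplicate_proteins(pool)

    catalog = MotifCatalog(dataset=dataset, source=source, k_set=k_set)
    for e in sorted(pool, key=lambda e: e.protein_id):
        _insert_entry(catalog, e)
    catalog.stats = catalog.rebuild_stats()
    return catalog


def _insert_entry(catalog: MotifCatalog, entry: ProteinEntry) -> None:
    catalog.proteins[entry.protein_id] = ProteinInfo(
        entry.protein_id, entry.source, entry.engineered, entry.mutated,
        entry.has_nucleic_link, entry.chain_sequence_digest())
    for k in catalog.k_set:
        catalog.records.extend(extract_all(entry, k))


def merge_update(catalog: MotifCatalog,
                 new_entries: Sequence[ProteinEntry]) -> MotifCatalog:
    """Incremental update: append records for genuinely new protein ids and
    update the statistics; already-present ids are skipped, so re-merging
    the same entries never double-counts. One structured log line is emitted
    per inserted or skipped entry; an entry whose extraction fails is logged
    and skipped without aborting the merge.

    On a NONREDUNDANT catalog a new entry whose sequence content duplicates
    a protein already in the catalog (or an earlier new entry) is skipped.
    """
    merged = MotifCatalog(dataset=catalog.dataset, source=catalog.source,
                          k_set=catalog.k_set,
                          records=list(catalog.records),
                          stats=dict(catalog.stats),
                          proteins=dict(catalog.proteins))
    digests = {info.seq_digest: pid for pid, info in merged.proteins.items()}

    candidates = {}
    for e in new_entries:
        if e.protein_id in merged.proteins or e.protein_id in candidates:
            logger.info("skipped %s: already present", e.protein_id)
            continue
        candidates[e.protein_id] = e

    for pid in sorted(candidates):
        e = candidates[pid]
        if e.source is not merged.source:
            logger.error("error %s: source %s does not match catalog %s",
                         pid, e.source.value, merged.source.value)
            continue
        if merged.dataset is Dataset.NONREDUNDANT:
            digest = e.chain_sequence_digest()
            if digest in digests:
                logger.info("skipped %s: duplicate sequence of %s", pid, digests[digest])
                continue
            digests[digest] = pid
        try:
            new_records = [rec for k in merged.k_set for rec in extract_all(e, k)]
        except Exception as exc:
            logger.error("error %s: %s", pid, exc)
            continue
        merged.proteins[pid] = ProteinInfo(pid, e.source, e.engineered, e.mutated,
                                           e.has_nucleic_link,
                                           e.chain_sequence_digest())
        merged.records.extend(new_records)
        for rec in new_records:
            key = (rec.motif, rec.k)
            prev = merged.stats.get(key)
            add_b = 1 if rec.site.state is BondState.BONDED else 0
            if prev is None:
                merged.stats[key] = MotifStats(rec.motif, rec.k, 1, add_b)
            else:
                merged.stats[key] = MotifStats(rec.motif, rec.k,
                                               prev.total + 1, prev.bonded + add_b)
        logger.info("inserted %s (%d motif records)", pid, len(new_records))
    merged.stats = dict(sorted(merged.stats.items()))
    return merged


@dataclass
class PropensityTable:
    """Per-offset relative amino-acid frequencies around the cysteine,
    for the whole population and for the bonded subpopulation.

    Offsets run -k..-1, +1..+k (the centre is always C and is omitted);
    '-' padding is excluded from the denominators, so each non-empty column
    sums to 1. This positional-frequency reading of "propensity" is an
    interpretation; see the methods note.
    """

    k: int
    freq_all: pd.DataFrame     # index: amino acid, columns: offsets
    freq_bonded: pd.DataFrame


def positional_propensity(catalog: MotifCatalog, k: int) -> PropensityTable:
    if k not in catalog.k_set:
        raise ValueError(f"catalog has no records at flank width {k}")
    offsets = [o for o in range(-k, k + 1) if o != 0]
    letters = sorted(set(AMINO_ACIDS) | {"X"})
    counts_all = pd.DataFrame(0, index=letters, columns=offsets, dtype=float)
    counts_bonded = counts_all.copy()
    for rec in catalog.records:
        if rec.k != k:
            continue
        for o in offsets:
            aa = rec.motif[k + o]
            if aa == "-":
                continue
            counts_all.loc[aa, o] += 1
            if rec.site.state is BondState.BONDED:
                counts_bonded.loc[aa, o] += 1
    return PropensityTable(k, _normalise(counts_all), _normalise(counts_bonded))


def _normalise(counts: pd.DataFrame) -> pd.DataFrame:
    sums = counts.sum(axis=0)
    # empty columns stay all-zero rather than NaN
    return counts.div(sums.where(sums > 0, other=1.0), axis=1)


# ---------------------------------------------------------------------------
# persistence: TSV tables (records, stats, proteins) + a small JSON header

_META = "catalog.json"
_RECORDS = "records.tsv"
_STATS = "stats.tsv"
_PROTEINS = "proteins.tsv"


def records_frame(records: Sequence[MotifRecord]) -> pd.DataFrame:
    rows = [{
        "protein_id": r.site.protein_id,
        "chain_id": r.site.chain_id,
        "position": r.site.position,
        "k": r.k,
        "motif": r.motif,
        "ss": r.ss,
        "state": r.site.state.value,
        "scope": r.site.scope.value if r.site.scope else "",
        "partner": f"{r.site.partner[0]}:{r.site.partner[1]}" if r.site.partner else "",
    } for r in records]
    return pd.DataFrame(rows, columns=["protein_id", "chain_id", "position", "k",
                                       "motif", "ss", "state", "scope", "partner"])


def stats_frame(stats: dict[tuple[str, int], MotifStats]) -> pd.DataFrame:
    rows = [{
        "motif": s.motif, "k": s.k, "total": s.total, "bonded": s.bonded,
        "coefficient": render_coefficient(s.coefficient), "class": s.cls.value,
    } for _, s in sorted(stats.items())]
    return pd.DataFrame(rows, columns=["motif", "k", "total", "bonded",
                                       "coefficient", "class"])


def save_catalog(catalog: MotifCatalog, directory: str | Path) -> Path:
    """Persist a catalog as TSV tables plus a JSON header; the canonical,
    bit-exact interchange form."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / _META).write_text(json.dumps({
        "format": "cysmotif-catalog/1",
        "dataset": catalog.dataset.value,
        "source": catalog.source.value,
        "k_set": list(catalog.k_set),
    }, indent=2) + "\n")
    records_frame(catalog.records).to_csv(directory / _RECORDS, sep="\t", index=False)
    stats_frame(catalog.stats).to_csv(directory / _STATS, sep="\t", index=False)
    prot = pd.DataFrame([{
        "protein_id": p.protein_id, "source": p.source.value,
        "engineered": p.engineered, "mutated": p.mutated,
        "has_nucleic_link": p.has_nucleic_link, "seq_digest": p.seq_digest,
    } for p in sorted(catalog.proteins.values(), key=lambda p: p.protein_id)],
        columns=["protein_id", "source", "engineered", "mutated",
                 "has_nucleic_link", "seq_digest"])
    prot.to_csv(directory / _PROTEINS, sep="\t", index=False)
    return directory


def load_catalog(directory: str | Path) -> MotifCatalog:
    directory = Path(directory)
    meta_path = directory / _META
    if not meta_path.exists():
        raise FileNotFoundError(f"no catalog at {directory} (missing {_META})")
    meta = json.loads(meta_path.read_text())
    catalog = MotifCatalog(dataset=Dataset(meta["dataset"]),
                           source=Source(meta["source"]),
                           k_set=tuple(meta["k_set"]))
    rec_df = pd.read_csv(directory / _RECORDS, sep="\t",
                         dtype={"scope": str, "partner": str, "ss": str},
                         keep_default_na=False)
    for row in rec_df.itertuples(index=False):
        partner = None
        if row.partner:
            pc, _, pp = row.partner.rpartition(":")
            partner = (pc, int(pp))
        site = CysteineSite(str(row.protein_id), str(row.chain_id), int(row.position),
                            BondState(row.state), partner,
                            BondScope(row.scope) if row.scope else None)
        catalog.records.append(MotifRecord(str(row.motif), int(row.k), site, str(row.ss)))
    prot_df = pd.read_csv(directory / _PROTEINS, sep="\t", keep_default_na=False)
    for row in prot_df.itertuples(index=False):
        catalog.proteins[str(row.protein_id)] = ProteinInfo(
            str(row.protein_id), Source(row.source), _parse_bool(row.engineered),
            _parse_bool(row.mutated), _parse_bool(row.has_nucleic_link),
            str(row.seq_digest))
    catalog.stats = catalog.rebuild_stats()
    return catalog


def _parse_bool(value) -> bool:
    return str(value).strip().lower() == "true"
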